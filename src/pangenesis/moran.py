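"""Forward-time neutral simulator: Moran birth-death plus gene transfer.

A population of N organisms, each carrying exactly M distinct genes, evolves
by a Gillespie event loop over three Poisson event classes:

* reproduction (total rate N*rho): a uniformly chosen organism dies and is
  replaced by a copy of a uniformly chosen *other* organism;
* gene transfer (total rate N*sigma): a uniformly chosen organism gains a
  brand-new gene (an identifier never seen in the population before,
  infinitely-many-genes style) which displaces a uniformly chosen resident
  gene, keeping genome size at M;
* pure birth (total rate N*alpha, optional): a copy of a uniformly chosen
  organism is added without a death, so the census size grows exponentially
  at rate alpha in expectation.  This forward growth variant is a validation
  aid; the exponential-growth spectrum itself is computed backward in time by
  the coalescent module.

The simulator is the brute-force oracle for the closed-form spectra and the
package's synthetic-data generator: sampled presence/absence matrices behave
like empirical gene-cluster tables with the effective transfer parameter
theta = N*sigma/(M*rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fluidity import PresenceAbsenceMatrix
from .spectra import GeneFrequencySpectrum

__all__ = ["SimConfig", "PopulationState", "run", "sample_genomes",
           "stationary_spectrum_mc"]

_BUF = 1 << 16


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    N0: initial population size (>= 2); M: genes per genome; rho/sigma/alpha:
    per-individual rates (time^-1) of reproduction, gene transfer and pure
    birth (population growth); init_mode: "identical" (clonal start, the
    default, appropriate for stationarity runs after burn-in) or
    "all_distinct" (every gene in every genome unique); seed: RNG seed.
    """

    N0: int
    M: int
    rho: float = 1.0
    sigma: float = 0.0
    alpha: float = 0.0
    init_mode: str = "identical"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N0 < 2:
            raise ValueError(f"N0 must be >= 2, got {self.N0}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        for name in ("rho", "sigma", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.init_mode not in ("identical", "all_distinct"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


class PopulationState:
    """Mutable population: N genomes of M globally tracked gene identifiers.

    Genomes are rows of a preallocated integer array; every transfer event
    consumes a fresh identifier from a global counter, so an identifier never
    recurs once lost.  Each genome holds exactly M distinct genes at all
    times.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.M = config.M
        self.N = config.N0
        cap = max(2 * config.N0, config.N0 + 64)
        self._genomes = np.empty((cap, config.M), dtype=np.int64)
        if config.init_mode == "identical":
            self._genomes[: self.N] = np.arange(config.M, dtype=np.int64)
            self.next_gene_id = config.M
        else:  # all_distinct
            ids = np.arange(config.N0 * config.M, dtype=np.int64)
            self._genomes[: self.N] = ids.reshape(config.N0, config.M)
            self.next_gene_id = config.N0 * config.M
        self.time = 0.0
        self.event_counts = {"reproduction": 0, "transfer": 0, "birth": 0}
        self.rng = np.random.default_rng(config.seed)
        self._buf = np.empty(0)
        self._i = 0

    @property
    def genomes(self) -> np.ndarray:
        """View of the live N x M genome array."""
        return self._genomes[: self.N]

    def _u(self) -> float:
        if self._i >= self._buf.size:
            self._buf = self.rng.random(_BUF)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return v

    def _grow_capacity(self) -> None:
        new = np.empty((2 * self._genomes.shape[0], self.M), dtype=np.int64)
        new[: self.N] = self._genomes[: self.N]
        self._genomes = new

    def advance(self, duration: float | None = None,
                n_events: int | None = None) -> None:
        """Run the Gillespie loop for a time span and/or an event budget."""
        if duration is None and n_events is None:
            raise ValueError("specify duration and/or n_events")
        t_end = math.inf if duration is None else self.time + duration
        budget = math.inf if n_events is None else n_events
        cfg = self.config
        rho, sigma, alpha = cfg.rho, cfg.sigma, cfg.alpha
        per_cap = rho + sigma + alpha
        if per_cap == 0.0:
            if duration is not None:
                self.time = t_end
            return
        p_rep = rho / per_cap
        p_trans = (rho + sigma) / per_cap
        G_ = self._genomes
        log = math.log
        done = 0
        while done < budget:
            N = self.N
            dt = -log(1.0 - self._u()) / (N * per_cap)
            if self.time + dt > t_end:
                self.time = t_end
                return
            self.time += dt
            u = self._u()
            if u < p_rep:
                die = int(self._u() * N)
                par = int(self._u() * (N - 1))
                if par >= die:
                    par += 1
                G_[die] = G_[par]
                self.event_counts["reproduction"] += 1
            elif u < p_trans:
                ind = int(self._u() * N)
                pos = int(self._u() * self.M)
                G_[ind, pos] = self.next_gene_id
                self.next_gene_id += 1
                self.event_counts["transfer"] += 1
            else:
                par = int(self._u() * N)
                if N >= G_.shape[0]:
                    self._grow_capacity()
                    G_ = self._genomes
                G_[N] = G_[par]
                self.N = N + 1
                self.event_counts["birth"] += 1
            done += 1

    def summary(self) -> dict:
        """Event-log summary (counts by type, elapsed time, census size)."""
        return {"time": self.time, "N": self.N,
                "genes_introduced": int(self.next_gene_id),
                **self.event_counts}


def run(config: SimConfig, duration: float | None = None,
        n_events: int | None = None) -> PopulationState:
    """Simulate a fresh population for a duration and/or event count."""
    state = PopulationState(config)
    state.advance(duration=duration, n_events=n_events)
    return state


def sample_genomes(state: PopulationState, G: int,
                   rng: np.random.Generator | None = None) -> PresenceAbsenceMatrix:
    """Sample G genomes uniformly without replacement as a binary matrix.

    Columns (genomes) all sum to M; rows cover the union of genes present in
    the sample.
    """
    if G > state.N:
        raise ValueError(f"cannot sample G={G} genomes from population of {state.N}")
    if rng is None:
        rng = state.rng
    idx = rng.choice(state.N, size=G, replace=False)
    sample = state.genomes[idx]
    ids, inverse = np.unique(sample, return_inverse=True)
    inverse = inverse.reshape(G, state.M)
    data = np.zeros((ids.size, G), dtype=np.int8)
    for j in range(G):
        data[inverse[j], j] = 1
    return PresenceAbsenceMatrix(
        data,
        gene_names=[f"g{int(i)}" for i in ids],
        genome_names=[f"genome{int(i)}" for i in idx],
    )


def _sample_spectrum_counts(state: PopulationState, G: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Occupancy histogram of a uniform G-genome sample (fast path).

    Genes are distinct within a genome, so concatenated-id multiplicities
    equal presence counts.
    """
    idx = rng.choice(state.N, size=G, replace=False)
    ids = state.genomes[idx].ravel()
    _, counts = np.unique(ids, return_counts=True)
    return np.bincount(counts, minlength=G + 1)[1:].astype(float)


def _timescale(config: SimConfig) -> float:
    """Characteristic relaxation time N0/rho (or 1/sigma if rho = 0)."""
    if config.rho > 0:
        return config.N0 / config.rho
    if config.sigma > 0:
        return 1.0 / config.sigma
    return 1.0


def stationary_spectrum_mc(
    config: SimConfig,
    G: int,
    n_epochs: int = 200,
    burn_in: float = 10.0,
    spacing: float = 0.5,
) -> GeneFrequencySpectrum:
    """Time-averaged sampled spectrum of a stationary population.

    Runs a single chain, discards ``burn_in`` relaxation times (units of
    N0/rho), then draws a fresh uniform G-genome sample every ``spacing``
    relaxation times for ``n_epochs`` epochs.  Returns the mean spectrum with
    per-bin standard errors (std over epochs / sqrt(n_epochs); epochs at the
    default spacing are close to independent, so the SEs are only mildly
    optimistic).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if burn_in < 0 or spacing <= 0:
        raise ValueError("burn_in must be >= 0 and spacing > 0")
    if G > config.N0:
        raise ValueError("G exceeds population size")
    unit = _timescale(config)
    state = PopulationState(config)
    state.advance(duration=burn_in * unit)
    acc = np.zeros((n_epochs, G))
    for e in range(n_epochs):
        if e > 0:
            state.advance(duration=spacing * unit)
        acc[e] = _sample_spectrum_counts(state, G, state.rng)
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / math.sqrt(n_epochs) if n_epochs > 1 else np.zeros(G)
    return GeneFrequencySpectrum(mean, config.M, se=se)


def _pan_core_epochs(config: SimConfig, G_max: int,
                     n_reps: int) -> tuple[np.ndarray, np.ndarray]:
    """Observed pan/core curves over random genome orderings at stationarity.

    For each epoch, samples G_max genomes without replacement (in random
    order) and records the running union (pan) and intersection (core) sizes
    as genomes accumulate.  Returns (n_reps, G_max) arrays.
    """
    unit = _timescale(config)
    state = PopulationState(config)
    state.advance(duration=10.0 * unit)
    pan = np.zeros((n_reps, G_max))
    core = np.zeros((n_reps, G_max))
    for r in range(n_reps):
        if r > 0:
            state.advance(duration=0.5 * unit)
        idx = state.rng.choice(state.N, size=G_max, replace=False)
        union = set(state.genomes[idx[0]].tolist())
        inter = set(union)
        pan[r, 0] = core[r, 0] = len(union)
        for j in range(1, G_max):
            genome = set(state.genomes[idx[j]].tolist())
            union |= genome
            inter &= genome
            pan[r, j] = len(union)
            core[r, j] = len(inter)
    return pan, core
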