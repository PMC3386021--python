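"""Closed-form gene frequency spectra for neutral pan-genome models.

The central object is the gene frequency spectrum: given a sample of ``G``
genomes, each carrying ``M`` genes, ``g[k]`` is the (expected or observed)
number of distinct genes present in exactly ``k`` of the ``G`` genomes.

Model A is the stationary, constant-population-size neutral model: a Moran
population of ``N`` organisms in which gene transfer introduces a brand-new
gene at rate ``sigma`` per individual (displacing a random resident gene, so
genome size stays ``M``) while reproduction occurs at rate ``rho`` per
individual.  Only the dimensionless combination ``theta = N*sigma/(M*rho)``
enters the expected spectrum, which takes the Ewens (infinitely-many-alleles)
form

    g_k = (M*theta/k) * G!/(G-k)! * (theta)_{G-k} / (theta)_G,

with ``(theta)_k = theta*(theta+1)*...*(theta+k-1)`` the rising factorial.
The spectrum is U-shaped for ``theta < 1`` and monotonically decreasing for
``theta > 1``.

Models C and D partition each genome into two compartments evolving
independently under model A: model C has a perfectly rigid core (transfer
parameter zero for a fraction ``lambda2`` of the genome), model D a flexible
core with a smaller but non-zero transfer parameter ``theta2 <= theta1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "THETA_CAP",
    "GeneFrequencySpectrum",
    "ModelAParams",
    "ModelCParams",
    "ModelDParams",
    "spectrum_model_a",
    "spectrum_model_c",
    "spectrum_model_d",
    "pan_core_curves",
    "pan_core_band_model_d",
]

logger = logging.getLogger(__name__)

#: Transfer parameters above this value are treated as the theta -> infinity
#: limit (every gene private to the genome that carries it).  Fitted values at
#: the cap are rendered as "inf" in reports.
THETA_CAP = 1e6


@dataclass
class GeneFrequencySpectrum:
    """Gene frequency spectrum of a sample of ``G`` genomes.

    Parameters
    ----------
    g
        Length-``G`` vector; ``g[k-1]`` is the number of distinct genes found
        in exactly ``k`` genomes (real-valued for model predictions, integer
        counts for observations).  Genes absent from the sample (k = 0) are
        never stored.
    M
        Genes per genome.  For empirical data this may be the mean genome
        size and need not be an integer.
    se
        Optional per-bin Monte Carlo standard errors (predictions obtained by
        simulation).
    genome_sizes
        Optional raw per-genome gene counts (column sums of the source
        presence/absence matrix); retained for fluidity computations.
    """

    g: np.ndarray
    M: float
    se: np.ndarray | None = None
    genome_sizes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1 or self.g.size < 1:
            raise ValueError("spectrum must be a non-empty 1-D vector")
        if np.any(self.g < 0) or not np.all(np.isfinite(self.g)):
            raise ValueError("spectrum entries must be finite and >= 0")
        if not (self.M > 0):
            raise ValueError(f"M must be positive, got {self.M}")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.g.shape:
                raise ValueError("se must match spectrum length")

    @property
    def G(self) -> int:
        """Number of sampled genomes."""
        return int(self.g.size)

    @property
    def k(self) -> np.ndarray:
        """Occupancy values 1..G (1-based bin labels)."""
        return np.arange(1, self.G + 1)

    def total_gene_mass(self) -> float:
        """Sum of k*g_k; equals G*M for any conservative model/sample."""
        return float(np.sum(self.k * self.g))

    def pan_size(self) -> float:
        """Observed pan genome size: number of distinct genes in the sample."""
        return float(self.g.sum())

    def core_size(self) -> float:
        """Observed core genome size: genes present in every genome."""
        return float(self.g[-1])


def _validate_theta(theta: float, name: str = "theta") -> float:
    if theta is None or (isinstance(theta, float) and math.isnan(theta)):
        raise ValueError(f"{name} must be a number")
    if theta < 0:
        raise ValueError(f"{name} must be >= 0, got {theta}")
    if math.isinf(theta) or theta > THETA_CAP:
        if math.isfinite(theta):
            logger.info("%s=%g exceeds cap %g; using infinite-transfer limit",
                        name, theta, THETA_CAP)
        return math.inf
    return float(theta)


@dataclass(frozen=True)
class ModelAParams:
    """Constant-population-size model: one effective transfer rate theta."""

    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", _validate_theta(self.theta))


@dataclass(frozen=True)
class ModelCParams:
    """Rigid-core model: fluid fraction ``lambda1`` with rate ``theta1``,
    rigid fraction ``lambda2 = 1 - lambda1`` never touched by transfer."""

    theta1: float
    lambda1: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta1", _validate_theta(self.theta1, "theta1"))
        if not (0.0 <= self.lambda1 <= 1.0):
            raise ValueError(f"lambda1 must be in [0, 1], got {self.lambda1}")

    @property
    def lambda2(self) -> float:
        return 1.0 - self.lambda1


@dataclass(frozen=True)
class ModelDParams:
    """Flexible-core model: two compartments with rates theta1 >= theta2."""

    theta1: float
    theta2: float
    lambda1: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta1", _validate_theta(self.theta1, "theta1"))
        object.__setattr__(self, "theta2", _validate_theta(self.theta2, "theta2"))
        if not (0.0 <= self.lambda1 <= 1.0):
            raise ValueError(f"lambda1 must be in [0, 1], got {self.lambda1}")
        if self.theta2 > self.theta1:
            raise ValueError(
                f"theta2 ({self.theta2}) must not exceed theta1 ({self.theta1})"
            )

    @property
    def lambda2(self) -> float:
        return 1.0 - self.lambda1


def _model_a_vector(theta: float, M: float, G: int) -> np.ndarray:
    """Expected spectrum vector for model A (no dataclass wrapping).

    Evaluated in log space,

        log g_k = log M + log theta - log k + lnG(G+1) - lnG(G-k+1)
                  + lnG(theta+G-k) - lnG(theta+G),

    which is finite and accurate for G up to at least 1e3 and theta up to the
    internal cap.  theta = 0 and theta = inf are explicit limits.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    if not (M > 0):
        raise ValueError(f"M must be positive, got {M}")
    theta = _validate_theta(theta)
    g = np.zeros(G)
    if theta < 1e-300:  # gammaln overflows on subnormals; limit is exact to eps
        g[G - 1] = M
        return g
    if math.isinf(theta):
        g[0] = M * G
        return g
    k = np.arange(1, G + 1, dtype=float)
    logg = (
        math.log(M)
        + math.log(theta)
        - np.log(k)
        + gammaln(G + 1)
        - gammaln(G - k + 1)
        + gammaln(theta + (G - k))  # grouping keeps tiny theta from absorbing
        - gammaln(theta + G)
    )
    return np.exp(logg)


def spectrum_model_a(theta: float, M: float, G: int) -> GeneFrequencySpectrum:
    """Expected gene frequency spectrum of the constant-size neutral model.

    Parameters
    ----------
    theta
        Effective gene transfer rate ``N*sigma/(M*rho)`` (>= 0; values above
        the internal cap are treated as infinite).
    M
        Genes per genome.
    G
        Sample size (number of genomes), >= 1.

    Returns
    -------
    GeneFrequencySpectrum
        Expected counts; satisfies ``sum(k*g_k) == G*M`` exactly.
    """
    return GeneFrequencySpectrum(_model_a_vector(theta, M, G), M)


def spectrum_model_c(params: ModelCParams, M: float, G: int) -> GeneFrequencySpectrum:
    """Rigid-core spectrum: model A on the fluid fraction plus a core spike.

    The fluid compartment (``lambda1*M`` genes per genome, rate ``theta1``)
    follows model A; the rigid core contributes ``lambda2*M`` genes present in
    all ``G`` genomes.  Non-integer compartment sizes are kept real: the
    spectrum is an expectation, not a count.
    """
    if not isinstance(params, ModelCParams):
        params = ModelCParams(*params)
    if not (M > 0):
        raise ValueError(f"M must be positive, got {M}")
    g = np.zeros(G)
    if params.lambda1 > 0:
        g = _model_a_vector(params.theta1, params.lambda1 * M, G)
    g[G - 1] += params.lambda2 * M
    return GeneFrequencySpectrum(g, M)


def spectrum_model_d(params: ModelDParams, M: float, G: int) -> GeneFrequencySpectrum:
    """Flexible-core spectrum: sum of two model-A spectra.

    Compartment 1 has ``lambda1*M`` genes at rate ``theta1``; compartment 2
    has ``lambda2*M`` genes at rate ``theta2 <= theta1``.  ``theta2 = 0``
    degenerates to model C, ``theta1 = theta2`` to model A.
    """
    if not isinstance(params, ModelDParams):
        params = ModelDParams(*params)
    if not (M > 0):
        raise ValueError(f"M must be positive, got {M}")
    g = np.zeros(G)
    if params.lambda1 > 0:
        g += _model_a_vector(params.theta1, params.lambda1 * M, G)
    if params.lambda2 > 0:
        g += _model_a_vector(params.theta2, params.lambda2 * M, G)
    return GeneFrequencySpectrum(g, M)


def _pan_core_model_a(theta: float, M: float, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form expected pan/core sizes for model A at sample sizes ``n``.

    pan(n) = M * sum_{i=0}^{n-1} theta/(theta+i)  (the i=0 term is 1)
    core(n) = g_n of the size-n spectrum = M*theta*(n-1)!/(theta)_n.
    """
    theta = _validate_theta(theta)
    nf = n.astype(float)
    if theta == 0.0:
        return np.full(n.shape, M, dtype=float), np.full(n.shape, M, dtype=float)
    if math.isinf(theta):
        pan = M * nf
        core = np.where(n == 1, float(M), 0.0)
        return pan, core
    from scipy.special import digamma

    # sum_{i=0}^{n-1} 1/(theta+i) = psi(theta+n) - psi(theta)
    pan = M * theta * (digamma(theta + nf) - digamma(theta))
    # core(n) = M*theta*(n-1)!/(theta)_n with (theta)_n = Gamma(theta+n)/Gamma(theta)
    core = np.exp(math.log(M) + math.log(theta) + gammaln(nf)
                  - (gammaln(theta + nf) - gammaln(theta)))
    return pan, core


def pan_core_curves(
    params: ModelAParams | ModelDParams | float,
    M: float,
    G_max: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected pan and core genome sizes at sample sizes n = 1..G_max.

    pan(n) is the expected number of distinct genes in a sample of n genomes
    (grows like ``M*theta*ln(n)`` for model A); core(n) is the expected number
    of genes shared by all n (decays like ``M*Gamma(theta+1)*n**-theta``).
    For model D the curves are the lambda-weighted sums of the per-compartment
    model-A curves.  ``pan(1) == core(1) == M`` always.
    """
    if G_max < 1:
        raise ValueError(f"G_max must be >= 1, got {G_max}")
    if not (M > 0):
        raise ValueError(f"M must be positive, got {M}")
    n = np.arange(1, G_max + 1)
    if isinstance(params, (int, float)):
        params = ModelAParams(params)
    if isinstance(params, ModelAParams):
        return _pan_core_model_a(params.theta, M, n)
    if isinstance(params, ModelCParams):
        params = ModelDParams(params.theta1, 0.0, params.lambda1)
    if not isinstance(params, ModelDParams):
        raise TypeError(f"unsupported parameter object: {params!r}")
    pan = np.zeros(G_max)
    core = np.zeros(G_max)
    for lam, th in ((params.lambda1, params.theta1), (params.lambda2, params.theta2)):
        if lam > 0:
            p, c = _pan_core_model_a(th, lam * M, n)
            pan += p
            core += c
    return pan, core


def pan_core_band_model_d(
    params: ModelDParams,
    M: float,
    G_max: int,
    n_reps: int = 500,
    seed: int | None = None,
    N: int | None = None,
) -> dict[str, np.ndarray]:
    """Monte Carlo mean and SD of observed pan/core curves under model D.

    Draws samples of ``G_max`` genomes from stationary forward-simulated
    populations (one Moran + transfer population per genome compartment, with
    matched theta and compartment size), accumulates genomes in random order,
    and records the running pan and core sizes.  Genome 1 of each sample is a
    random draw, so ``core_sd[0]`` and ``pan_sd[0]`` are 0 (a single genome
    always carries exactly M genes).

    Returns a dict with keys ``pan_mean, pan_sd, core_mean, core_sd``
    (length-``G_max`` vectors, sample-size axis n = 1..G_max).
    """
    from .moran import SimConfig, run, _pan_core_epochs

    if not isinstance(params, ModelDParams):
        params = ModelDParams(*params)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if G_max < 1:
        raise ValueError("G_max must be >= 1")
    rng = np.random.default_rng(seed)
    if N is None:
        N = max(4 * G_max, 40)

    comps = []
    for lam, th in ((params.lambda1, params.theta1), (params.lambda2, params.theta2)):
        m = int(round(lam * M))
        if m >= 1:
            comps.append((m, th))
    # pan/core of the union genome = sum over independent compartments
    pan = np.zeros((n_reps, G_max))
    core = np.zeros((n_reps, G_max))
    for m, th in comps:
        if th == 0.0 or math.isinf(th):
            # degenerate compartments need no simulation
            if th == 0.0:
                pan += m
                core += m
            else:
                pan += m * np.arange(1, G_max + 1)
                core[:, 0] += m
            continue
        sigma = th * m / N  # rho = 1
        cfg = SimConfig(N0=N, M=m, rho=1.0, sigma=sigma,
                        seed=int(rng.integers(2**31 - 1)))
        p, c = _pan_core_epochs(cfg, G_max, n_reps)
        pan += p
        core += c
    return {
        "pan_mean": pan.mean(axis=0),
        "pan_sd": pan.std(axis=0, ddof=1),
        "core_mean": core.mean(axis=0),
        "core_sd": core.std(axis=0, ddof=1),
    }
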