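"""Model B: gene frequency spectrum under exponential population growth.

The population history is N(t) = N0 * exp(alpha*(t - t0)).  Backward in
time the sample genealogy is an inhomogeneous Kingman coalescent: in the
dimensionless time tau in which a pair of lineages coalesces at rate 1 at
the present, the pair rate at depth tau is exp(beta*tau), where
beta = N0*alpha/(2*rho) is the population growth parameter.  Gene content
evolves along the tree under the infinitely-many-genes process calibrated so
that beta = 0 reproduces the constant-size (Ewens-form) spectrum exactly:

* the root genome carries exactly M genes (equivalent to integrating the
  stem acquisition process at stationarity);
* new genes are acquired along each branch as a Poisson process with rate
  M*theta0/2 per unit tau;
* each gene present on a lineage is lost at rate theta0/2 per unit tau, and
  a loss removes it from every leaf below that point,

with theta0 = N0*sigma/(M*rho) the present-day transfer parameter.

The expected spectrum for a *given* tree is computed exactly by a subtree
dynamic program (no gene-level sampling); Monte Carlo noise enters only
through tree randomness, and per-bin standard errors over trees are
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import GeneFrequencySpectrum

__all__ = ["ModelBParams", "CoalescentTree", "simulate_tree",
           "spectrum_model_b", "estimate_rare_gene_exponent"]


@dataclass(frozen=True)
class ModelBParams:
    """theta0: present-day transfer parameter; beta: growth parameter.

    beta = 0 reduces to the constant-population-size model with
    theta = theta0.
    """

    theta0: float
    beta: float

    def __post_init__(self) -> None:
        if self.theta0 < 0:
            raise ValueError(f"theta0 must be >= 0, got {self.theta0}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class CoalescentTree:
    """Binary rooted genealogy of G leaves, ultrametric at the leaves.

    Nodes 0..G-1 are leaves (time 0); internal node ``G+i`` is created by the
    i-th coalescence with children ``children[i]`` at backward time
    ``times[G+i]``.  Children always have smaller indices (and times) than
    their parent; the root is node ``2G-2``.
    """

    G: int
    children: np.ndarray  # (G-1, 2) node indices
    times: np.ndarray     # (2G-1,) backward times, leaves at 0

    def __post_init__(self) -> None:
        if self.children.shape != (self.G - 1, 2):
            raise ValueError("children must have shape (G-1, 2)")
        for i, (c1, c2) in enumerate(self.children):
            v = self.G + i
            if self.times[v] <= max(self.times[c1], self.times[c2]):
                raise ValueError("parent time must exceed child times")

    @property
    def root(self) -> int:
        return 2 * self.G - 2

    @property
    def root_height(self) -> float:
        return float(self.times[self.root])

    def total_branch_length(self) -> float:
        total = 0.0
        for i, (c1, c2) in enumerate(self.children):
            tv = self.times[self.G + i]
            total += (tv - self.times[c1]) + (tv - self.times[c2])
        return float(total)

    def to_newick(self) -> str:
        """Newick string with branch lengths in dimensionless tau units."""

        def render(v: int) -> str:
            if v < self.G:
                return f"L{v}"
            c1, c2 = self.children[v - self.G]
            tv = self.times[v]
            return (f"({render(c1)}:{tv - self.times[c1]:.6g},"
                    f"{render(c2)}:{tv - self.times[c2]:.6g})")

        return render(self.root) + ";"


def simulate_tree(G: int, beta: float,
                  rng: np.random.Generator | None = None) -> CoalescentTree:
    """Simulate one genealogy under exponential growth.

    With j lineages at depth tau, the next coalescence occurs after a waiting
    time solving the inhomogeneous-exponential integral

        integral_tau^{tau+w} (j(j-1)/2) e^{beta s} ds = E,  E ~ Exp(1),

    inverted in closed form; a uniformly random pair then merges.  beta = 0
    is the standard constant-rate coalescent (pair rate 1).
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    active = list(range(G))
    children = np.empty((G - 1, 2), dtype=np.int64)
    times = np.zeros(2 * G - 1)
    tau = 0.0
    for i in range(G - 1):
        j = len(active)
        npairs = j * (j - 1) / 2.0
        E = rng.exponential()
        if beta == 0.0:
            tau += E / npairs
        else:
            tau = math.log(math.exp(beta * tau) + beta * E / npairs) / beta
        a = int(rng.integers(j))
        b = int(rng.integers(j - 1))
        if b >= a:
            b += 1
        c1, c2 = active[a], active[b]
        v = G + i
        children[i] = (c1, c2)
        times[v] = tau
        active[max(a, b)] = v
        del active[min(a, b)]
    return CoalescentTree(G, children, times)


def _tree_expected_spectrum(tree: CoalescentTree, theta0: float,
                            M: float) -> np.ndarray:
    """Exact expected spectrum for one tree (subtree dynamic program).

    For each node v, p[v][k] is the probability that a gene present at v
    survives in exactly k of the leaves below it (k = 0..n_v), built bottom-up
    by convolving the two child-edge contributions (loss on the edge sends a
    gene to k = 0).  Root genes contribute M * p[root][k]; genes gained on
    the edge above node c contribute M*(1 - exp(-theta0*l/2)) * p[c][k]
    (the integral over gain positions collapses because the edge does not
    branch).  O(G^2) per tree.
    """
    G = tree.G
    half = 0.5 * theta0
    p: list[np.ndarray | None] = [None] * (2 * G - 1)
    leaf = np.array([0.0, 1.0])
    for v in range(G):
        p[v] = leaf
    g = np.zeros(G + 1)
    for i in range(G - 1):
        v = G + i
        tv = tree.times[v]
        qs = []
        for c in tree.children[i]:
            length = tv - tree.times[c]
            s = math.exp(-half * length)
            pc = p[c]
            q = s * pc
            q[0] += 1.0 - s  # lost on the edge -> 0 surviving leaves
            qs.append(q)
            # genes gained on this edge that survive to c
            g[1: pc.size] += M * (1.0 - s) * pc[1:]
            p[c] = None  # free
        p[v] = np.convolve(qs[0], qs[1])
    g[1:] += M * p[tree.root][1:]
    return g[1:]


def spectrum_model_b(
    params: ModelBParams,
    M: float,
    G: int,
    n_trees: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> GeneFrequencySpectrum:
    """Monte Carlo average spectrum over coalescent genealogies.

    Averages the exact per-tree expected spectrum over ``n_trees`` simulated
    trees; the returned spectrum carries per-bin standard errors across
    trees.  Identical seeds give bit-identical output.
    """
    if not isinstance(params, ModelBParams):
        params = ModelBParams(*params)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if G < 2:
        raise ValueError("G must be >= 2")
    if not (M > 0):
        raise ValueError("M must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    acc = np.empty((n_trees, G))
    for t in range(n_trees):
        tree = simulate_tree(G, params.beta, rng)
        acc[t] = _tree_expected_spectrum(tree, params.theta0, M)
    mean = acc.mean(axis=0)
    se = (acc.std(axis=0, ddof=1) / math.sqrt(n_trees)
          if n_trees > 1 else np.zeros(G))
    return GeneFrequencySpectrum(mean, M, se=se)


def estimate_rare_gene_exponent(spectrum: GeneFrequencySpectrum,
                                k_max: int) -> float:
    """Fit g_k ~ k**-gamma on the rare-gene flank and return gamma.

    Least squares of log g_k on log k over k = 1..k_max.  The constant-size
    model gives gamma ~= 1; population growth steepens the flank
    (gamma > 1).
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    if k_max > spectrum.G:
        raise ValueError("k_max exceeds spectrum length")
    g = spectrum.g[:k_max]
    if np.any(g <= 0):
        raise ValueError(
            "zero counts in 1..k_max; truncate k_max below the first empty bin"
        )
    k = np.arange(1, k_max + 1, dtype=float)
    slope = np.polyfit(np.log(k), np.log(g), 1)[0]
    return float(-slope)
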