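"""Genomic fluidity: average gene-content dissimilarity of genome pairs.

Genomic fluidity phi is the probability that a randomly chosen gene from one
genome of a pair is absent from the other.  For a sample of G genomes it is
estimated by averaging, over all G(G-1)/2 unordered pairs, the ratio of the
number of genes unique to either genome (U_k + U_l) to the total gene count
of the pair (M_k + M_l).

Under the stationary constant-population-size neutral model the population
fluidity is an exact algebraic function of the effective transfer rate:
phi = theta/(1+theta), i.e. theta = phi/(1-phi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import GeneFrequencySpectrum

__all__ = [
    "PresenceAbsenceMatrix",
    "fluidity_observed",
    "fluidity_from_theta",
    "theta_from_fluidity",
    "fluidity_expected_from_spectrum",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary gene presence/absence matrix: rows = genes, columns = genomes.

    ``data[i, j] == 1`` iff gene (cluster) ``i`` is present in genome ``j``.
    Column sums are the per-genome gene counts ``M_j`` (need not be equal for
    empirical data); no all-zero rows are allowed (a gene absent from every
    genome is not observable).
    """

    data: np.ndarray
    gene_names: list[str] | None = None
    genome_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x genomes)")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self.data = self.data.astype(np.int8)
        if self.data.shape[0] and np.any(self.data.sum(axis=1) == 0):
            n0 = int(np.sum(self.data.sum(axis=1) == 0))
            raise ValueError(f"matrix contains {n0} all-zero gene rows")
        if self.gene_names is not None and len(self.gene_names) != self.data.shape[0]:
            raise ValueError("gene_names length mismatch")
        if self.genome_names is not None and len(self.genome_names) != self.data.shape[1]:
            raise ValueError("genome_names length mismatch")

    @property
    def n_genes(self) -> int:
        return int(self.data.shape[0])

    @property
    def G(self) -> int:
        return int(self.data.shape[1])

    def genome_sizes(self) -> np.ndarray:
        """Per-genome gene counts M_j (column sums)."""
        return self.data.sum(axis=0).astype(int)


def fluidity_observed(matrix: PresenceAbsenceMatrix) -> float:
    """Exact sample genomic fluidity.

    Averages (U_k + U_l)/(M_k + M_l) over all unordered genome pairs, where
    U are the genes unique to one genome of the pair and M the genome sizes.
    Requires G >= 2 and no empty genomes.
    """
    if not isinstance(matrix, PresenceAbsenceMatrix):
        matrix = PresenceAbsenceMatrix(np.asarray(matrix))
    X = matrix.data.astype(np.int64)
    G = matrix.G
    if G < 2:
        raise ValueError("fluidity requires at least 2 genomes")
    sizes = X.sum(axis=0)
    if np.any(sizes == 0):
        raise ValueError("fluidity undefined for empty genomes")
    shared = X.T @ X                      # pairwise intersection sizes
    tot = sizes[:, None] + sizes[None, :]  # M_k + M_l
    uniq = tot - 2 * shared                # U_k + U_l
    iu = np.triu_indices(G, k=1)
    return float(np.mean(uniq[iu] / tot[iu]))


def fluidity_from_theta(theta: float) -> float:
    """Stationary-model fluidity phi = theta/(1+theta)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if np.isinf(theta):
        return 1.0
    return theta / (1.0 + theta)


def theta_from_fluidity(phi: float) -> float:
    """Invert phi = theta/(1+theta): theta = phi/(1-phi).  Requires phi < 1."""
    if not (0.0 <= phi < 1.0):
        raise ValueError(f"phi must be in [0, 1), got {phi} (theta diverges at 1)")
    return phi / (1.0 - phi)


def fluidity_expected_from_spectrum(spectrum: GeneFrequencySpectrum) -> float:
    """Expected fluidity of an exchangeable sample with equal genome sizes.

    For a gene present in k of G genomes, a random pair of genomes contains it
    in exactly one member with probability k(G-k) / (G(G-1)/2) / 2 ... summing
    over genes gives

        phi = sum_k g_k * k * (G - k) / (M * G * (G - 1)).

    Applied to the model-A spectrum this reproduces theta/(1+theta) exactly;
    it is the route used for model-predicted fluidities.
    """
    G = spectrum.G
    if G < 2:
        raise ValueError("expected fluidity requires G >= 2")
    k = spectrum.k.astype(float)
    return float(np.sum(spectrum.g * k * (G - k)) / (spectrum.M * G * (G - 1)))
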