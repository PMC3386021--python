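"""File formats: spectrum and presence/absence tables, config files.

Canonical dialects
------------------
Spectrum file
    Two columns ``k<TAB>count`` (header optional), k strictly increasing
    within 1..G.  Missing k rows are implicit zeros; G is the largest k
    present.  Predictions are written with 6 significant digits.
Matrix file
    Genes as rows, genomes as columns, 0/1 integer cells, tab-delimited
    (comma accepted), UTF-8; first column gene names, first row genome
    names.  A Roary-style ``gene_presence_absence.csv`` is accepted as a
    dialect: known annotation columns are dropped and any non-empty cell in
    a genome column counts as presence.
Config file
    Flat YAML mapping of CLI option names to values; command-line flags
    override config values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fluidity import PresenceAbsenceMatrix
from .spectra import GeneFrequencySpectrum

__all__ = [
    "spectrum_from_matrix",
    "read_spectrum", "write_spectrum",
    "read_matrix", "write_matrix",
    "read_config",
]

#: Annotation columns of a Roary gene_presence_absence.csv (not genomes).
_ROARY_META_COLS = {
    "Gene", "Non-unique Gene name", "Annotation", "No. isolates",
    "No. sequences", "Avg sequences per isolate", "Genome Fragment",
    "Order within Fragment", "Accessory Fragment",
    "Accessory Order with Fragment", "QC", "Min group size nuc",
    "Max group size nuc", "Avg group size nuc",
}


class ParseError(ValueError):
    """Malformed spectrum/matrix file (message carries the line number)."""


def spectrum_from_matrix(matrix: PresenceAbsenceMatrix) -> GeneFrequencySpectrum:
    """Histogram of gene occupancies: g_k = number of rows with sum k.

    M is set to the mean genome size (rounded); the raw per-genome sizes are
    retained on the spectrum for exact fluidity work.  Rows summing to zero
    are rejected (with their count) — an unobserved gene cannot appear in the
    table.
    """
    if not isinstance(matrix, PresenceAbsenceMatrix):
        matrix = PresenceAbsenceMatrix(np.asarray(matrix))
    rowsums = matrix.data.sum(axis=1)
    n_zero = int(np.sum(rowsums == 0))
    if n_zero:
        raise ValueError(f"{n_zero} gene rows have zero occupancy")
    G = matrix.G
    g = np.bincount(rowsums, minlength=G + 1)[1:].astype(float)
    sizes = matrix.genome_sizes()
    M = max(1.0, round(float(sizes.mean())))
    return GeneFrequencySpectrum(g, M, genome_sizes=sizes)


def _sniff_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head or "," not in head else ","


def read_spectrum(path: str | Path) -> GeneFrequencySpectrum:
    """Read a two-column k/count spectrum file (gaps = implicit zeros)."""
    path = Path(path)
    ks: list[int] = []
    counts: list[float] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p for p in (q.strip() for q in parts) if p]
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, "
                                 f"got {len(parts)}")
            try:
                k = int(parts[0])
                c = float(parts[1])
            except ValueError:
                if lineno == 1 and not ks:
                    continue  # header row
                raise ParseError(f"{path}:{lineno}: non-numeric row {parts!r}")
            if c < 0:
                raise ParseError(f"{path}:{lineno}: negative count {c}")
            if k < 1:
                raise ParseError(f"{path}:{lineno}: k must be >= 1, got {k}")
            if ks and k <= ks[-1]:
                raise ParseError(f"{path}:{lineno}: k values must be strictly "
                                 f"increasing (k={k} after k={ks[-1]})")
            ks.append(k)
            counts.append(c)
    if not ks:
        raise ParseError(f"{path}: no data rows")
    G = ks[-1]
    g = np.zeros(G)
    for k, c in zip(ks, counts):
        g[k - 1] = c
    M = max(1.0, float(np.sum(np.arange(1, G + 1) * g)) / G)
    return GeneFrequencySpectrum(g, M)


def write_spectrum(spectrum: GeneFrequencySpectrum, path: str | Path,
                   header: bool = True) -> None:
    """Write a spectrum as k<TAB>count; predictions get 6 significant digits."""
    path = Path(path)
    integral = np.allclose(spectrum.g, np.round(spectrum.g))
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("k\tcount\n" if integral else "k\tg_pred\n")
        for k, c in zip(spectrum.k, spectrum.g):
            fh.write(f"{k}\t{int(round(c))}\n" if integral else f"{k}\t{c:.6g}\n")


def read_matrix(path: str | Path) -> PresenceAbsenceMatrix:
    """Read a presence/absence table (plain binary or Roary-style CSV)."""
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no genome columns found")
    genome_cols = [c for c in df.columns if c not in _ROARY_META_COLS]
    if not genome_cols:
        raise ParseError(f"{path}: only annotation columns present")
    sub = df[genome_cols]
    values = sub.to_numpy()
    stripped = np.char.strip(values.astype(str))
    numeric = np.char.isdigit(np.char.replace(stripped, ".", ""))
    if numeric.all():
        # plain numeric table: entries must be strictly binary
        bad = ~np.isin(stripped, ("0", "1"))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"{path}: non-binary entry {stripped[i, j]!r} at data line "
                f"{int(i) + 2}, column {genome_cols[int(j)]!r}")
        data = stripped.astype(np.int8)
    else:
        # Roary dialect: any non-empty cell marks presence
        data = (stripped != "").astype(np.int8)
    bad = np.where(data.sum(axis=1) == 0)[0]
    if bad.size:
        raise ParseError(
            f"{path}: {bad.size} gene rows with no presence "
            f"(first at data line {int(bad[0]) + 2})")
    return PresenceAbsenceMatrix(data, gene_names=[str(i) for i in sub.index],
                                 genome_names=[str(c) for c in genome_cols])


def write_matrix(matrix: PresenceAbsenceMatrix, path: str | Path) -> None:
    """Write the canonical tab-delimited 0/1 table (genes x genomes)."""
    path = Path(path)
    genes = matrix.gene_names or [f"gene{i}" for i in range(matrix.n_genes)]
    genomes = matrix.genome_names or [f"genome{j}" for j in range(matrix.G)]
    df = pd.DataFrame(matrix.data, index=genes, columns=genomes)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    """Load a flat YAML mapping of option names to values."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
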