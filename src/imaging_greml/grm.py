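"""Genomic relationship matrix: construction, relatedness pruning, PCA, I/O.

The GRM entry for individuals j, k is the average over SNPs of
(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)), with allele frequencies
p_i estimated in-sample after QC and missing dosages mean-imputed (they
contribute zero to the numerator and are excluded from the per-pair SNP
count).  The text exchange format is the GCTA triplet dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, QcError
from .genotypes import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric relatedness matrix with per-pair SNP counts and sample ids."""

    values: np.ndarray
    nsnp: np.ndarray
    sample_ids: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nsnp = np.asarray(self.nsnp)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.nsnp.shape != (n, n):
            raise ConfigError("GRM matrices must be square and congruent")
        if len(self.sample_ids) != n:
            raise ConfigError("sample id count does not match GRM size")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("GRM contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def take(self, idx: np.ndarray) -> "GRM":
        return GRM(
            self.values[np.ix_(idx, idx)],
            self.nsnp[np.ix_(idx, idx)],
            self.sample_ids.iloc[idx].reset_index(drop=True),
        )


def compute_grm(g: GenotypeMatrix) -> GRM:
    """Build the GRM from a QC'd dosage matrix.

    Raises if any SNP is monomorphic in-sample (the MAF filter must run
    first); symmetry is enforced exactly.
    """
    freq = g.allele_frequencies()
    if np.any(np.isnan(freq)) or np.any((freq <= 0) | (freq >= 1)):
        raise QcError(
            "monomorphic or all-missing SNP reached compute_grm; "
            "apply the MAF filter first"
        )
    X = g.dosages
    obs = ~np.isnan(X)
    W = (np.where(obs, X, 2 * freq) - 2 * freq) / np.sqrt(
        2 * freq * (1 - freq)
    )
    nsnp = obs.astype(np.int32) @ obs.astype(np.int32).T
    if np.any(nsnp == 0):
        raise QcError("a sample pair shares no genotyped SNP")
    A = (W @ W.T) / nsnp
    A = (A + A.T) / 2.0
    return GRM(A, nsnp, g.sample_ids.copy())


def prune_related(grm: GRM, cutoff: float = 0.05) -> pd.DataFrame:
    """Greedily drop individuals until no retained pair exceeds the cutoff.

    At each step the individual participating in the most over-cutoff pairs
    is removed; ties break toward the lower sample index.  Returns the
    retained sample ids, indexed by their original positions.
    """
    over = np.triu(grm.values > cutoff, k=1)
    over = over | over.T
    keep = np.ones(grm.n, dtype=bool)
    counts = over.sum(axis=1).astype(int)
    while True:
        counts_masked = np.where(keep, counts, -1)
        worst = int(np.argmax(counts_masked))
        if counts_masked[worst] <= 0:
            break
        keep[worst] = False
        counts = counts - over[worst].astype(int)
        counts[~keep] = 0
        over[worst, :] = False
        over[:, worst] = False
    idx = np.flatnonzero(keep)
    out = grm.sample_ids.iloc[idx].copy()
    out.index = idx
    return out


def grm_pca(grm: GRM, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of the double-centered relatedness matrix.

    Returns (scores, eigenvalues) with eigenvalues in descending order and
    each eigenvector oriented so its largest-magnitude loading is positive.
    Eigenvectors are orthonormal; ties in the spectrum keep scipy's ordering.
    """
    if k >= grm.n:
        raise ConfigError(f"k must be < n (got k={k}, n={grm.n})")
    n = grm.n
    J = np.eye(n) - np.ones((n, n)) / n
    Ac = J @ grm.values @ J
    Ac = (Ac + Ac.T) / 2.0
    vals, vecs = np.linalg.eigh(Ac)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = pd.DataFrame(
        vecs, columns=[f"PC{i + 1}" for i in range(k)]
    )
    scores.insert(0, "fid", grm.sample_ids["fid"].to_numpy())
    scores.insert(1, "iid", grm.sample_ids["iid"].to_numpy())
    return scores, vals


def write_grm(grm: GRM, prefix) -> tuple[Path, Path]:
    """Write GCTA text-triplet files ``{prefix}.grm`` and ``{prefix}.grm.id``.

    Rows are (index1, index2, nsnp, value) for the lower triangle including
    the diagonal, 1-based indices; values at 6 significant decimals.
    """
    prefix = Path(prefix)
    grm_path = Path(str(prefix) + ".grm")
    id_path = Path(str(prefix) + ".grm.id")
    with open(grm_path, "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(
                    f"{i + 1}\t{j + 1}\t{int(grm.nsnp[i, j])}\t"
                    f"{grm.values[i, j]:.6e}\n"
                )
    grm.sample_ids[["fid", "iid"]].to_csv(
        id_path, sep="\t", header=False, index=False
    )
    return grm_path, id_path


def read_grm(prefix) -> GRM:
    """Read the GCTA text-triplet pair written by :func:`write_grm`."""
    prefix = Path(prefix)
    grm_path = Path(str(prefix) + ".grm")
    id_path = Path(str(prefix) + ".grm.id")
    ids = pd.read_csv(id_path, sep="\t", header=None, names=["fid", "iid"],
                      dtype=str)
    n = len(ids)
    tab = pd.read_csv(
        grm_path, sep="\t", header=None,
        names=["i", "j", "nsnp", "value"],
    )
    if tab["i"].max() != n or len(tab) != n * (n + 1) // 2:
        raise ParseError(
            f"{grm_path}: triplet rows inconsistent with {n} ids"
        )
    values = np.zeros((n, n))
    nsnp = np.zeros((n, n), dtype=np.int64)
    ii = tab["i"].to_numpy() - 1
    jj = tab["j"].to_numpy() - 1
    values[ii, jj] = tab["value"].to_numpy()
    values[jj, ii] = values[ii, jj]
    nsnp[ii, jj] = tab["nsnp"].to_numpy()
    nsnp[jj, ii] = nsnp[ii, jj]
    return GRM(values, nsnp, ids)
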