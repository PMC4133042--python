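"""Genotype container, PLINK text I/O and per-SNP / per-sample quality control.

Dosages are stored as a float matrix counting copies of the coded (minor)
allele, with ``nan`` marking missing calls.  QC follows the conventional
microarray sequence: SNP missingness, Hardy-Weinberg exact test, minor allele
frequency, and a per-sample call-rate filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError

_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class GenotypeMatrix:
    """n-subject x m-SNP minor-allele dosage matrix with SNP metadata.

    ``snp_meta`` columns: id, chrom, pos, allele1 (coded/minor), allele2,
    and optionally p_gen (the generating allele frequency for simulated
    panels).  ``sample_ids`` columns: fid, iid.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.snp_meta) != m:
            raise ConfigError("snp_meta length does not match dosage columns")
        if len(self.sample_ids) != n:
            raise ConfigError("sample_ids length does not match dosage rows")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Coded-allele frequency per SNP, computed on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of dosage (0, 1, 2) on non-missing calls; shape m x 3."""
        out = np.zeros((self.m, 3), dtype=int)
        for k in range(3):
            out[:, k] = np.nansum(self.dosages == k, axis=0)
        return out

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.snp_meta.loc[mask].reset_index(drop=True),
            self.sample_ids,
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[mask, :],
            self.snp_meta,
            self.sample_ids.loc[mask].reset_index(drop=True),
        )


@dataclass
class QcReport:
    """Ordered record of filters applied, thresholds used and removals."""

    axis: str  # "snp" or "sample"
    n_input: int
    steps: list[tuple[str, float, int]] = field(default_factory=list)

    def add(self, name: str, threshold: float, n_removed: int) -> None:
        self.steps.append((name, threshold, n_removed))

    @property
    def n_removed(self) -> int:
        return sum(s[2] for s in self.steps)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "threshold", "n_removed"]
        ).assign(axis=self.axis, n_input=self.n_input, n_retained=self.n_retained)


def parse_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read whitespace-delimited PED/MAP files into a GenotypeMatrix.

    The minor allele per SNP is determined from the in-file allele counts
    (ties broken toward the lexicographically later allele) and becomes the
    coded allele; '0 0' genotypes become missing.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{map_path}: line {ln}: expected 4 fields")
        map_rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    m = len(map_rows)

    fams, a1_cols, a2_cols = [], [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, "
                f"got {len(parts)}"
            )
        alleles = parts[6:]
        for j, a in enumerate(alleles):
            if a not in _VALID_ALLELES and a != "0":
                raise ParseError(
                    f"{ped_path}: line {ln}: invalid allele code {a!r}"
                )
        pair1, pair2 = alleles[0::2], alleles[1::2]
        for j in range(m):
            if (pair1[j] == "0") != (pair2[j] == "0"):
                raise ParseError(
                    f"{ped_path}: line {ln}: half-missing genotype at SNP {j + 1}"
                )
        fams.append(parts[:6])
        a1_cols.append(pair1)
        a2_cols.append(pair2)

    n = len(fams)
    A1 = np.array(a1_cols, dtype="U1")
    A2 = np.array(a2_cols, dtype="U1")
    dosages = np.full((n, m), np.nan)
    minor_alleles, major_alleles = [], []
    for j in range(m):
        obs = np.concatenate([A1[:, j], A2[:, j]])
        obs = obs[obs != "0"]
        alleles, counts = np.unique(obs, return_counts=True)
        if alleles.size == 0:
            minor, major = "0", "0"
        elif alleles.size == 1:
            minor, major = alleles[0], alleles[0]
        elif alleles.size == 2:
            # minor = rarer allele; tie -> lexicographically later
            order = np.lexsort((alleles, counts))
            if counts[order[0]] == counts[order[1]]:
                minor = max(alleles)
            else:
                minor = alleles[order[0]]
            major = alleles[0] if alleles[1] == minor else alleles[1]
        else:
            raise ParseError(f"SNP {j + 1} has more than two alleles")
        minor_alleles.append(minor)
        major_alleles.append(major)
        miss = A1[:, j] == "0"
        dosages[~miss, j] = (
            (A1[~miss, j] == minor).astype(float)
            + (A2[~miss, j] == minor).astype(float)
        )
        if alleles.size == 1:
            # monomorphic: dosage counts the single observed allele (freq 1)
            dosages[~miss, j] = 2.0

    meta = pd.DataFrame(
        {
            "id": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "pos": [r[3] for r in map_rows],
            "allele1": minor_alleles,
            "allele2": major_alleles,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f[0] for f in fams], "iid": [f[1] for f in fams]}
    )
    return GenotypeMatrix(dosages, meta, samples)


def write_plink_text(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PED/MAP text files; returns (ped_path, map_path)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for _, row in g.snp_meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    a1 = g.snp_meta["allele1"].to_numpy()
    a2 = g.snp_meta["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(g.n):
            fid = g.sample_ids["fid"].iat[i]
            iid = g.sample_ids["iid"].iat[i]
            fields = [str(fid), str(iid), "0", "0", "0", "-9"]
            d = g.dosages[i]
            for j in range(g.m):
                if np.isnan(d[j]):
                    fields += ["0", "0"]
                elif d[j] == 0:
                    fields += [a2[j], a2[j]]
                elif d[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    counts (same parity as the minor-allele count) under the conditional
    distribution given allele counts, and sums the probabilities of all
    outcomes no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ConfigError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ConfigError("at least one genotype is required")
    n_a = 2 * n_aa + n_Aa  # copies of one allele
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, rare) up to a constant:
    #   P(h) propto n! 2^h / ( ((rare-h)/2)! h! ((2n-rare-h)/2)! )
    hom_rare = (rare - hets) // 2
    hom_common = (2 * n - rare - hets) // 2
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_rare + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_Aa][0]
    return float(np.clip(p[p <= p_obs * (1 + 1e-12)].sum(), 0.0, 1.0))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def apply_snp_qc(
    g: GenotypeMatrix,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """SNP filters in order: missingness > miss_max, HWE p <= hwe_p_min,
    MAF < maf_min.  Counts in the report are order-dependent."""
    for name, t in (("miss_max", miss_max), ("hwe_p_min", hwe_p_min),
                    ("maf_min", maf_min)):
        if not (0.0 <= t <= 1.0):
            raise ConfigError(f"{name} must lie in [0, 1], got {t}")
    if g.m == 0 or g.n == 0:
        raise ConfigError("empty genotype matrix")

    report = QcReport(axis="snp", n_input=g.m)

    miss = g.snp_missingness()
    keep = miss <= miss_max
    report.add("missingness", miss_max, int((~keep).sum()))
    g = g.take_snps(keep)

    counts = g.genotype_counts()
    hwe_p = np.ones(g.m)
    for j in range(g.m):
        if counts[j].sum() > 0:
            hwe_p[j] = hwe_exact_test(*counts[j])
    keep = hwe_p > hwe_p_min
    report.add("hwe", hwe_p_min, int((~keep).sum()))
    g = g.take_snps(keep)

    freq = g.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        keep = maf >= maf_min  # nan (all-missing SNP) compares False -> removed
    report.add("maf", maf_min, int((~keep).sum()))
    g = g.take_snps(keep)

    return g, report


def apply_sample_qc(
    g: GenotypeMatrix, call_rate_min: float = 0.97
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples with genotyping call rate strictly below the threshold."""
    if not (0.0 <= call_rate_min <= 1.0):
        raise ConfigError("call_rate_min must lie in [0, 1]")
    if g.m == 0 or g.n == 0:
        raise ConfigError("empty genotype matrix")
    report = QcReport(axis="sample", n_input=g.n)
    rate = g.sample_call_rate()
    keep = rate >= call_rate_min  # boundary retained: exclusion is strict "<"
    report.add("call_rate", call_rate_min, int((~keep).sum()))
    return g.take_samples(keep), report
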