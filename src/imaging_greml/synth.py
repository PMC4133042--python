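"""Synthetic cohort generator: genotypes, polygenic ROI phenotypes, BOLD runs.

Everything downstream of real data acquisition is testable against this
module because every quantity the pipeline estimates — allele frequencies,
SNP heritability, genetic correlations, nodal degree, connection
proportions, percent signal change — is planted here with known ground
truth.

Genotypes are Hardy-Weinberg draws (two Bernoulli(p) trials per SNP).
Phenotypes are GCTA-style polygenic traits: standard-normal effects on
standardized causal dosages, rescaled so the realized genetic variance is
exactly the target VG/Vp, plus cross-ROI correlated environmental noise.
BOLD runs carry an ongoing correlated-noise structure between connected ROI
pairs plus condition-locked activation placed 2 TRs after block onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (BLOCK_LEN, ROI_MEAN_BSC_AMBIGUOUS, SimConfig)
from .connectivity import RoiTimeSeries
from .exceptions import ConfigError, DecompositionError, DesignError
from .genotypes import GenotypeMatrix

_ALLELE_PAIRS = np.array([
    ("A", "G"), ("A", "C"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"),
])


def _rng(config: SimConfig, rng=None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


def simulate_genotypes(config: SimConfig, rng=None) -> GenotypeMatrix:
    """Draw an n x m dosage panel under Hardy-Weinberg sampling.

    Per SNP, a minor allele frequency p ~ U(maf_range) generates dosages as
    Binomial(2, p); the coded allele is the generating minor allele.
    Missingness, if configured, is injected completely at random.
    """
    rng = _rng(config, rng)
    n, m = config.n_subjects, config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
    pair = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    meta = pd.DataFrame(
        {
            "id": [f"snp{j + 1:06d}" for j in range(m)],
            "chrom": (np.arange(m) % 22 + 1).astype(str),
            "pos": (np.arange(m) + 1) * 1000,
            "allele1": pair[:, 0],
            "allele2": pair[:, 1],
            "p_gen": p,
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"FAM{i + 1:05d}" for i in range(n)],
            "iid": [f"IND{i + 1:05d}" for i in range(n)],
        }
    )
    return GenotypeMatrix(dosages, meta, samples)


def _standardized_dosages(genotypes: GenotypeMatrix,
                          cols: np.ndarray) -> np.ndarray:
    X = genotypes.dosages[:, cols].copy()
    mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    n_causal: int,
    h2: float,
    rng: np.random.Generator,
    causal_idx: np.ndarray | None = None,
    effects: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """One polygenic trait with realized VG/Vp equal to ``h2``.

    Returns (phenotype, truth) where truth records the causal indices, the
    rescaled effects and the genetic values.  Passing the same
    ``causal_idx``/``effects`` to a second call builds a trait with genetic
    correlation 1 to the first.
    """
    if n_causal > genotypes.m:
        raise ConfigError("n_causal cannot exceed the SNP count")
    if causal_idx is None:
        causal_idx = rng.choice(genotypes.m, size=n_causal, replace=False)
    causal_idx = np.asarray(causal_idx)
    if effects is None:
        effects = rng.standard_normal(causal_idx.size)
    Z = _standardized_dosages(genotypes, causal_idx)
    g = Z @ effects
    if h2 > 0 and g.std(ddof=0) > 0:
        scale = np.sqrt(h2) / g.std(ddof=0)
        g = g * scale
        effects = effects * scale
    else:
        g = np.zeros_like(g)
    e = rng.standard_normal(genotypes.n)
    e = (e - e.mean()) / e.std(ddof=0) * np.sqrt(max(1.0 - h2, 0.0))
    y = g + e
    truth = {"causal_idx": causal_idx, "effects": effects,
             "genetic_values": g, "h2": h2}
    return y, truth


@dataclass
class PhenotypePanel:
    """Multi-ROI phenotype table plus the generating ground truth."""

    table: pd.DataFrame
    genetic_values: np.ndarray
    truth: dict


def simulate_multiroi_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig, rng=None
) -> PhenotypePanel:
    """Polygenic phenotypes for every ROI with correlated environments.

    Each ROI has its own standard-normal effects on a shared causal SNP set;
    genetic values are rescaled so the realized VG/Vp equals that ROI's
    target.  The environmental component is multivariate normal across ROIs
    with correlation ``roi_pheno_corr``, scaled to variance (1 - h2) per
    ROI.  Site (with additive offsets) and sex labels are attached for
    covariate handling downstream.
    """
    rng = _rng(config, rng)
    n = genotypes.n
    R = config.roi_count
    h2 = config.h2_per_roi()

    C = np.asarray(config.roi_pheno_corr, dtype=float)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-8:
        raise DecompositionError(
            "roi_pheno_corr is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )
    L = np.linalg.cholesky(C + np.eye(R) * max(1e-10, -eigvals.min() + 1e-10))

    causal_idx = rng.choice(genotypes.m, size=config.n_causal, replace=False)
    Z = _standardized_dosages(genotypes, causal_idx)

    G = np.zeros((n, R))
    effects = np.zeros((config.n_causal, R))
    for r in range(R):
        beta = rng.standard_normal(config.n_causal)
        g = Z @ beta
        if h2[r] > 0 and g.std(ddof=0) > 0:
            scale = np.sqrt(h2[r]) / g.std(ddof=0)
            g *= scale
            beta = beta * scale
        else:
            g = np.zeros(n)
        G[:, r] = g
        effects[:, r] = beta

    E = rng.standard_normal((n, R)) @ L.T
    E = (E - E.mean(axis=0)) / E.std(axis=0, ddof=0)
    E = E * np.sqrt(np.clip(1.0 - h2, 0.0, None))

    site = rng.integers(0, config.n_sites, size=n)
    sex = rng.integers(0, 2, size=n)
    site_offsets = rng.normal(0.0, config.site_offset_sd, size=config.n_sites)

    Y = G + E + site_offsets[site][:, None] + config.sex_effect * sex[:, None]
    table = pd.DataFrame(Y, columns=list(config.roi_names))
    table.insert(0, "fid", genotypes.sample_ids["fid"].to_numpy())
    table.insert(1, "iid", genotypes.sample_ids["iid"].to_numpy())
    table.insert(2, "site", site)
    table.insert(3, "sex", sex)
    truth = {
        "causal_idx": causal_idx,
        "effects": effects,
        "h2": h2,
        "site_offsets": site_offsets,
    }
    return PhenotypePanel(table=table, genetic_values=G, truth=truth)


def simulate_subject_graph(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli draw of a subject's true connectivity graph (symmetric).

    A subject-level shift on the logit of every pair's connection
    probability (SD ``subject_connectivity_sd``) makes edges of one subject
    positively dependent, overdispersing nodal degree across subjects the
    way real cohorts are overdispersed relative to independent edges.
    Probabilities of 0 or 1 are deterministic and bypass the shift.
    """
    P = config.pair_connection_prob
    R = config.roi_count
    iu = np.triu_indices(R, k=1)
    p = P[iu]
    delta = (rng.normal(0.0, config.subject_connectivity_sd)
             if config.subject_connectivity_sd > 0 else 0.0)
    interior = (p > 0.0) & (p < 1.0)
    p_s = p.copy()
    if np.any(interior) and delta != 0.0:
        logit = np.log(p[interior] / (1.0 - p[interior]))
        p_s[interior] = 1.0 / (1.0 + np.exp(-(logit + delta)))
    edges = rng.random(p.size) < p_s
    adj = np.zeros((R, R), dtype=bool)
    adj[iu] = edges
    return adj | adj.T


def _psd_project(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= 1e-8:
        return C
    vals = np.clip(vals, 1e-8, None)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _edge_correlation_matrix(
    adj: np.ndarray, rho: float, nonedge_cap: float = 0.15, n_iter: int = 20
) -> np.ndarray:
    """Correlation matrix with ~rho on graph edges and small values elsewhere.

    The naive target (rho on edges, zero elsewhere) is not positive
    semi-definite for dense graphs, so the matrix is calibrated by
    alternating projections: project to the PSD cone (eigenvalue clipping +
    diagonal renormalization), reset edge entries to rho, and cap non-edge
    fill-in at ``nonedge_cap``.  For the standard design this keeps every
    edge correlation well above the 0.3 detection threshold and every
    non-edge correlation well below it; for sparse graphs (and complete
    graphs, which are equicorrelation-feasible) the target is met exactly.
    """
    R = adj.shape[0]
    off = ~adj & ~np.eye(R, dtype=bool)
    X = np.where(adj, rho, 0.0)
    np.fill_diagonal(X, 1.0)
    if np.linalg.eigvalsh(X).min() >= 1e-8:
        return X
    for _ in range(n_iter):
        C = _psd_project(X)
        X = C.copy()
        X[adj] = rho
        X[off] = np.clip(X[off], -nonedge_cap, nonedge_cap)
    return _psd_project(X)


def simulate_bold_session(
    config: SimConfig,
    subject_graph: np.ndarray,
    rng: np.random.Generator | None = None,
    subject: str = "SUBJ",
) -> RoiTimeSeries:
    """One subject's 160-volume run with planted connectivity and activation.

    Connected ROI pairs share correlated noise (coupling ``coupling_r``)
    throughout the run — functional connectivity is ongoing, so the
    condition-block correlations inherit it; unconnected pairs are
    independent.  Face blocks add a per-ROI activation amplitude placed
    ``2`` TRs after block onset, giving a known percent-signal-change
    ground truth.  WM/CSF channels are independent noise with configurable
    leakage into the ROI channels.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    design = config.block_design
    n_vol = design.size
    R = config.roi_count
    adj = np.asarray(subject_graph, dtype=bool)
    if adj.shape != (R, R):
        raise ConfigError("subject_graph has wrong shape")

    n_task = int(np.sum(design != "rest"))
    if n_task % BLOCK_LEN != 0:
        raise DesignError(
            f"task volumes ({n_task}) are not a whole number of "
            f"{BLOCK_LEN}-volume blocks"
        )

    C = _edge_correlation_matrix(adj, config.coupling_r)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(R))
    noise = (rng.standard_normal((n_vol, R)) @ L.T) * config.noise_sd

    amps = _activation_amplitudes(config)
    activation = np.zeros((n_vol, R))
    shift = 2
    for cond in ("ambiguous", "angry"):
        for s in _block_starts(design, cond):
            lo, hi = s + shift, min(s + shift + BLOCK_LEN, n_vol)
            activation[lo:hi, :] += amps[cond][None, :]

    wm = rng.standard_normal(n_vol) * config.noise_sd
    csf = rng.standard_normal(n_vol) * config.noise_sd
    leak = config.nuisance_leakage
    signal = (config.bold_baseline + activation + noise
              + leak * wm[:, None] + leak * csf[:, None])

    frame = pd.DataFrame(signal, columns=list(config.roi_names))
    frame["WM"] = config.bold_baseline + wm
    frame["CSF"] = config.bold_baseline + csf
    truth = {
        "adjacency": adj,
        "bsc": {c: 100.0 * amps[c] / config.bold_baseline
                for c in ("ambiguous", "angry")},
        "coupling_r": config.coupling_r,
    }
    return RoiTimeSeries(subject=subject, frame=frame, design=design,
                         truth=truth)


def _activation_amplitudes(config: SimConfig) -> dict[str, np.ndarray]:
    if config.bsc_amplitudes is not None:
        return {c: np.asarray(v, dtype=float)
                for c, v in config.bsc_amplitudes.items()}
    if config.roi_count == len(ROI_MEAN_BSC_AMBIGUOUS):
        base = np.asarray(ROI_MEAN_BSC_AMBIGUOUS)
    else:
        base = np.full(config.roi_count, 0.4)
    # amplitudes in raw signal units such that %BSC matches the target
    amb = base * config.bold_baseline / 100.0
    return {"ambiguous": amb, "angry": 0.6 * amb}


def _block_starts(design: np.ndarray, condition: str) -> list[int]:
    lab = np.asarray(design, dtype=object)
    hits = np.flatnonzero(lab == condition)
    starts = []
    prev = -2
    for h in hits:
        if h != prev + 1:
            starts.append(int(h))
        prev = h
    return starts


def simulate_bold_cohort(
    config: SimConfig, rng=None
) -> list[RoiTimeSeries]:
    """Independent runs for every subject, each with its own drawn graph."""
    rng = _rng(config, rng)
    out = []
    for i in range(config.n_subjects):
        adj = simulate_subject_graph(config, rng)
        out.append(
            simulate_bold_session(config, adj, rng=rng,
                                  subject=f"IND{i + 1:05d}")
        )
    return out


def write_phenotype_table(table: pd.DataFrame, path) -> None:
    """Phenotype TSV: FID, IID, site, sex, one column per ROI."""
    table.to_csv(path, sep="\t", index=False)


def write_bold_session(ts: RoiTimeSeries, signal_path, design_path) -> None:
    """Per-subject signal TSV (volumes x channels) and design TSV."""
    ts.frame.to_csv(signal_path, sep="\t", index=False)
    pd.DataFrame(
        {"volume": np.arange(ts.n_volumes), "block": ts.design}
    ).to_csv(design_path, sep="\t", index=False)
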