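"""Study-design constants and the simulation configuration object.

The defaults encode the study conditions the package emulates: a cohort of
unrelated adolescents genotyped on a common-SNP panel, a 25-node face-network
parcellation, and a six-minute block-design fMRI run (160 volumes at
TR = 2.2 s; 5 ambiguous-face, 5 angry-face and 9 non-biological-motion control
blocks of 8 volumes each, with rest padding at the end of the run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError

#: The 25 regions of interest of the face network, in the conventional order.
ROI_NAMES: tuple[str, ...] = (
    "L_MVLFC", "R_MVLFC", "L_MDLFC", "R_MDLFC", "L_PMC", "R_PMC", "R_PreSMA",
    "L_RhinalSulcus", "R_RhinalSulcus", "L_Amygdala", "R_Amygdala",
    "L_AntSTS", "R_AntSTS", "L_PostSTS", "R_PostSTS", "L_FFA", "R_FFA",
    "L_LOC", "R_LOC", "L_V2V3", "R_V2V3", "L_Cerebellum", "R_Cerebellum",
    "L_Putamen", "R_Putamen",
)

#: Published population mean percent BOLD signal change per ROI for the
#: ambiguous-faces-vs-control contrast; used as the default ground-truth
#: activation amplitudes of the BOLD simulator.
ROI_MEAN_BSC_AMBIGUOUS: tuple[float, ...] = (
    0.35, 0.43, 0.40, 0.56, 0.37, 0.44, 0.37, 0.17, 0.23, 0.37, 0.50, 0.27,
    0.44, 0.52, 0.73, 0.54, 0.64, 0.47, 0.58, 0.37, 0.37, 0.45, 0.22, 0.25,
    0.33,
)

#: Reported pairwise connection proportions among the eight ROIs that make up
#: the "Optional" (first four) and "Obligatory" (last four) subnetworks.
SUBNETWORK_ROIS: tuple[str, ...] = (
    "R_MVLFC", "L_MDLFC", "L_PMC", "R_AntSTS",
    "R_PostSTS", "R_FFA", "L_LOC", "R_LOC",
)

_SUBNETWORK_CONNECTION_PROPORTIONS = np.array([
    [1.00, 0.56, 0.30, 0.54, 0.61, 0.28, 0.30, 0.27],
    [0.56, 1.00, 0.60, 0.35, 0.45, 0.35, 0.31, 0.32],
    [0.30, 0.60, 1.00, 0.31, 0.49, 0.45, 0.48, 0.51],
    [0.54, 0.35, 0.31, 1.00, 0.65, 0.47, 0.37, 0.37],
    [0.61, 0.45, 0.49, 0.65, 1.00, 0.78, 0.69, 0.75],
    [0.28, 0.35, 0.45, 0.47, 0.78, 1.00, 0.85, 0.89],
    [0.30, 0.31, 0.48, 0.37, 0.69, 0.85, 1.00, 0.95],
    [0.27, 0.32, 0.51, 0.37, 0.75, 0.89, 0.95, 1.00],
], dtype=float)

#: Published population mean nodal degree per ROI (ambiguous contrast);
#: used to calibrate the default per-ROI connection propensities.
ROI_MEAN_DEGREE: tuple[float, ...] = (
    9.91, 10.20, 10.72, 11.43, 10.46, 11.83, 7.88, 5.48, 6.17, 7.36, 7.99,
    8.02, 10.45, 12.70, 14.03, 11.60, 12.20, 12.29, 12.21, 9.99, 9.81,
    11.22, 8.89, 7.64, 8.42,
)

#: Number of EPI volumes in one run and repetition time in seconds.
N_VOLUMES = 160
TR_SECONDS = 2.2
BLOCK_LEN = 8

CONDITIONS = ("ambiguous", "angry", "control")
REST_LABEL = "rest"


def default_block_design() -> np.ndarray:
    """Per-volume block labels for the standard 160-volume run.

    19 task blocks of 8 volumes (faces alternating with control, 9 control
    blocks interleaved) followed by 8 volumes of rest padding, so that the
    2-TR hemodynamic shift never runs off the end of the run.
    """
    order = []
    faces = ["ambiguous", "angry"] * 5
    for i in range(19):
        order.append(faces[i // 2] if i % 2 == 0 else "control")
    labels = [lab for lab in order for _ in range(BLOCK_LEN)]
    labels += [REST_LABEL] * (N_VOLUMES - len(labels))
    return np.array(labels, dtype=object)


def default_pair_connection_prob(
    roi_count: int = 25, background: float = 0.40
) -> np.ndarray:
    """Default per-pair connection probabilities (Table-1/2-analog).

    For the standard 25-ROI network, per-ROI connection propensities q_i are
    fitted by iterative proportional scaling so that the expected nodal
    degree sum(p_ij) = q_i q_j matches the published population mean degree
    of each ROI; the eight subnetwork ROIs then carry the published pairwise
    connection proportions.  Other network sizes get a uniform background
    probability.  Diagonal is zero (no self edges are simulated).
    """
    if roi_count != len(ROI_NAMES):
        P = np.full((roi_count, roi_count), background, dtype=float)
        np.fill_diagonal(P, 0.0)
        return P
    target = np.asarray(ROI_MEAN_DEGREE, dtype=float)
    q = np.sqrt(target / np.sqrt(target.mean() * roi_count))
    for _ in range(200):
        denom = q.sum() - q  # sum over partners j != i
        q = target / np.maximum(denom, 1e-9)
    P = np.clip(np.outer(q, q), 0.0, 0.97)
    np.fill_diagonal(P, 0.0)
    idx = [ROI_NAMES.index(r) for r in SUBNETWORK_ROIS]
    for a, i in enumerate(idx):
        for b, j in enumerate(idx):
            if i != j:
                P[i, j] = _SUBNETWORK_CONNECTION_PROPORTIONS[a, b]
    return P


def default_roi_pheno_corr(roi_count: int = 25, rho: float = 0.35) -> np.ndarray:
    """Default inter-ROI phenotypic correlation: exchangeable with ρ = 0.35.

    The regional responses of a subject are strongly positively correlated;
    an exchangeable structure at a moderate ρ is the simplest PSD stand-in.
    """
    C = np.full((roi_count, roi_count), rho, dtype=float)
    np.fill_diagonal(C, 1.0)
    return C


def expected_degree_variance(
    pair_connection_prob: np.ndarray, subject_sd: float = 1.0
) -> np.ndarray:
    """Expected per-ROI variance of nodal degree across subjects.

    Under edge-wise Bernoulli draws with a subject-level logit shift of
    standard deviation ``subject_sd``, the degree variance is approximately
    the binomial part Σ_j p(1−p) plus the overdispersion induced by the
    shared shift, ``subject_sd²·(Σ_j p(1−p))²`` (delta method: the edge
    probability moves by p(1−p) per unit logit).
    """
    P = np.asarray(pair_connection_prob, dtype=float)
    base = (P * (1.0 - P)).sum(axis=1)
    return base + subject_sd**2 * base**2


def degree_coupled_h2(
    pair_connection_prob: np.ndarray,
    h2_max: float = 0.5,
    subject_sd: float = 1.0,
) -> np.ndarray:
    """Per-ROI generating heritabilities coupled to expected degree variance.

    The study's central observation is that regions with the largest
    inter-individual variance in nodal degree carry the largest SNP-based
    heritability of their response.  To plant that structure, ROIs are
    ranked by expected degree variance and assigned VG/Vp values evenly
    spaced on [0, h2_max] in that order (ties broken by ROI index).
    """
    var = expected_degree_variance(pair_connection_prob, subject_sd)
    R = var.size
    order = np.argsort(var, kind="stable")
    h2 = np.empty(R)
    h2[order] = np.linspace(0.0, h2_max, R)
    return h2


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Parameters mirror the emulated study: ``n_subjects`` unrelated
    individuals, ``n_snps`` independent SNPs with minor allele frequencies
    uniform on ``maf_range``, ``n_causal`` causal SNPs per ROI phenotype and
    a generating SNP heritability ``target_h2`` (scalar, or one value per
    ROI).  ``pair_connection_prob`` governs which ROI pairs of a subject are
    functionally connected; ``roi_pheno_corr`` is the cross-ROI correlation
    of the environmental component of the phenotypes.
    """

    n_subjects: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 200
    target_h2: float | np.ndarray = 0.5
    roi_count: int = 25
    roi_pheno_corr: np.ndarray | None = None
    block_design: np.ndarray | None = None
    pair_connection_prob: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0
    missing_rate: float = 0.0
    n_sites: int = 8
    site_offset_sd: float = 0.3
    sex_effect: float = 0.0
    coupling_r: float = 0.5
    subject_connectivity_sd: float = 1.0
    bold_baseline: float = 100.0
    nuisance_leakage: float = 0.0
    bsc_amplitudes: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(
                f"maf_range must lie in (0, 0.5], got {self.maf_range}"
            )
        if self.n_causal > self.n_snps:
            raise ConfigError("n_causal cannot exceed n_snps")
        h2 = np.atleast_1d(np.asarray(self.target_h2, dtype=float))
        if np.any((h2 < 0) | (h2 > 1)):
            raise ConfigError("target_h2 must lie in [0, 1]")
        if h2.size not in (1, self.roi_count):
            raise ConfigError("target_h2 must be scalar or one value per ROI")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.roi_pheno_corr is None:
            self.roi_pheno_corr = default_roi_pheno_corr(self.roi_count)
        else:
            self.roi_pheno_corr = np.asarray(self.roi_pheno_corr, dtype=float)
            C = self.roi_pheno_corr
            if C.shape != (self.roi_count, self.roi_count):
                raise ConfigError("roi_pheno_corr has wrong shape")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ConfigError("roi_pheno_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-8):
                raise ConfigError("roi_pheno_corr must have unit diagonal")
        if self.block_design is None:
            self.block_design = default_block_design()
        else:
            self.block_design = np.asarray(self.block_design, dtype=object)
        if self.pair_connection_prob is None:
            self.pair_connection_prob = default_pair_connection_prob(
                self.roi_count
            )
        else:
            P = np.asarray(self.pair_connection_prob, dtype=float)
            if P.shape != (self.roi_count, self.roi_count):
                raise ConfigError("pair_connection_prob has wrong shape")
            if not np.allclose(P, P.T, atol=1e-10):
                raise ConfigError("pair_connection_prob must be symmetric")
            if np.any((P < 0) | (P > 1)):
                raise ConfigError(
                    "pair_connection_prob entries must lie in [0, 1]"
                )
            self.pair_connection_prob = P
        if not (0.0 <= self.coupling_r < 1.0):
            raise ConfigError("coupling_r must lie in [0, 1)")

    @property
    def roi_names(self) -> tuple[str, ...]:
        if self.roi_count == len(ROI_NAMES):
            return ROI_NAMES
        return tuple(f"ROI{i + 1:02d}" for i in range(self.roi_count))

    def h2_per_roi(self) -> np.ndarray:
        h2 = np.atleast_1d(np.asarray(self.target_h2, dtype=float))
        if h2.size == 1:
            return np.full(self.roi_count, float(h2[0]))
        return h2
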