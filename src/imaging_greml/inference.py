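"""Second-level statistics across the 25 ROIs.

Covers the count-of-significant-tests argument: the expected false-positive
count under the global null, a Monte-Carlo null for the observed count that
respects the phenotypic correlation between regions, trend regressions
linking heritability to network properties, the Optional/Obligatory
subnetwork classification, and split-half reproducibility of the regional
response profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .exceptions import ConfigError


def expected_false_positives(n_tests: int, alpha: float) -> float:
    """Expected count of nominally significant tests under the global null."""
    if n_tests < 0 or not (0.0 <= alpha <= 1.0):
        raise ConfigError("need n_tests >= 0 and alpha in [0, 1]")
    return n_tests * alpha


@dataclass
class CountNullDistribution:
    """Monte-Carlo null of the number of significant per-ROI tests."""

    alpha: float
    n_realizations: int
    histogram: np.ndarray  # counts of realizations with 0..k significant
    observed_count: int
    p_value: float
    method: str = "two-sided"

    def __post_init__(self) -> None:
        if int(self.histogram.sum()) != self.n_realizations:
            raise ConfigError("histogram must sum to n_realizations")


def mc_count_pvalue(
    corr: np.ndarray,
    observed_count: int,
    alpha: float = 0.05,
    n_realizations: int = 50_000,
    seed: int | np.random.Generator = 0,
    method: str = "two-sided",
) -> CountNullDistribution:
    """Monte-Carlo p-value for a count of significant correlated tests.

    Each realization draws one multivariate normal vector with the given
    correlation matrix, converts each coordinate to a null p-value
    (``two-sided`` normal, or ``boundary-mixture``: max(z,0)^2 against the
    0.5*chi2_0 + 0.5*chi2_1 null mirroring the GREML LRT), and counts
    coordinates significant at ``alpha``.  The returned p-value uses the
    add-one estimator (1 + #{count >= observed}) / (1 + n_realizations);
    a zero observed count therefore yields exactly 1.0.
    """
    C = np.asarray(corr, dtype=float)
    k = C.shape[0]
    if C.shape != (k, k) or not np.allclose(C, C.T, atol=1e-8):
        raise ConfigError("corr must be a symmetric square matrix")
    if not np.allclose(np.diag(C), 1.0, atol=1e-6):
        raise ConfigError("corr must have unit diagonal")
    if not (0 <= observed_count <= k):
        raise ConfigError(
            f"observed_count must lie in [0, {k}], got {observed_count}"
        )
    if method not in ("two-sided", "boundary-mixture"):
        raise ConfigError(f"unknown method {method!r}")

    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    if vals.min() < -1e-8:
        warnings.warn(
            "correlation matrix not PSD; nearest-PSD repair applied",
            RuntimeWarning, stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    L = vecs * np.sqrt(vals)

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Z = rng.standard_normal((n_realizations, k)) @ L.T
    if method == "two-sided":
        P = 2.0 * norm.sf(np.abs(Z))
    else:
        stat = np.clip(Z, 0.0, None) ** 2
        P = np.where(stat > 0, 0.5 * chi2.sf(stat, 1), 1.0)
    counts = (P < alpha).sum(axis=1)
    histogram = np.bincount(counts, minlength=k + 1)
    n_ge = int((counts >= observed_count).sum())
    p_value = (1 + n_ge) / (1 + n_realizations)
    if observed_count == 0:
        p_value = 1.0
    return CountNullDistribution(
        alpha=alpha, n_realizations=n_realizations, histogram=histogram,
        observed_count=observed_count, p_value=float(p_value), method=method,
    )


@dataclass
class TrendFit:
    """OLS trend across ROIs: coefficients, R^2 and the overall F test."""

    coefficients: np.ndarray
    r_squared: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float


def _ols_trend(X: np.ndarray, y: np.ndarray) -> TrendFit:
    model = sm.OLS(y, X).fit()
    df1 = int(model.df_model)
    df2 = int(model.df_resid)
    return TrendFit(
        coefficients=np.asarray(model.params),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df1=df1,
        df2=df2,
        p_value=float(model.f_pvalue),
    )


def fit_linear_trend(x, y) -> TrendFit:
    """OLS of y on [1, x]; F has (1, n-2) degrees of freedom."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ConfigError("x and y must be equal length with n >= 3")
    return _ols_trend(np.column_stack([np.ones_like(x), x]), y)


def fit_quadratic_trend(x, y) -> TrendFit:
    """OLS of y on [1, x, x^2]; F has (2, n-3) df — (2, 22) for 25 ROIs."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 4:
        raise ConfigError("x and y must be equal length with n >= 4")
    return _ols_trend(np.column_stack([np.ones_like(x), x, x**2]), y)


@dataclass
class SubnetworkLabels:
    """Per-ROI assignment to the Optional / Obligatory subnetworks."""

    labels: pd.Series  # values in {"Optional", "Obligatory", "Neither"}
    params: dict = field(default_factory=dict)

    def rois(self, which: str) -> list:
        return list(self.labels.index[self.labels == which])


def classify_subnetworks(
    stats: pd.DataFrame,
    k: int = 4,
    mean_band: tuple[float, float] = (0.25, 0.75),
    sd_tertile: float = 1.0 / 3.0,
    mean_col: str = "degree_mean",
    sd_col: str = "degree_sd",
) -> SubnetworkLabels:
    """Label ROIs as Optional / Obligatory / Neither from degree statistics.

    Optional: the k ROIs with the highest degree SD among those whose mean
    degree lies within the interquartile band of means (high variance,
    intermediate mean).  Obligatory: the k ROIs with the highest mean degree
    among the lowest-SD tertile (high mean, low variance).  Ties break
    toward the lower ROI index; the rule parameters are recorded in the
    result for reproducibility.
    """
    if k < 0:
        raise ConfigError("k must be >= 0")
    means = stats[mean_col].to_numpy(dtype=float)
    sds = stats[sd_col].to_numpy(dtype=float)
    index = stats.index
    labels = pd.Series("Neither", index=index, name="subnetwork")
    params = {"k": k, "mean_band": mean_band, "sd_tertile": sd_tertile}
    if k == 0:
        return SubnetworkLabels(labels, params)
    if np.ptp(means) == 0 and np.ptp(sds) == 0:
        warnings.warn(
            "degree statistics are identical across ROIs; no subnetworks",
            RuntimeWarning, stacklevel=2,
        )
        return SubnetworkLabels(labels, params)

    lo, hi = np.quantile(means, mean_band)
    optional_pool = np.flatnonzero((means >= lo) & (means <= hi))
    if optional_pool.size < k:
        raise ConfigError(
            f"only {optional_pool.size} ROIs fall in the mean band; "
            f"feasible k <= {optional_pool.size}"
        )
    # stable sort: descending SD, ties toward lower index
    order = optional_pool[np.lexsort((optional_pool, -sds[optional_pool]))]
    optional = order[:k]
    labels.iloc[optional] = "Optional"

    sd_cut = np.quantile(sds, sd_tertile)
    oblig_pool = np.array(
        [i for i in np.flatnonzero(sds <= sd_cut) if i not in set(optional)]
    )
    if oblig_pool.size < k:
        raise ConfigError(
            f"only {oblig_pool.size} ROIs fall in the low-SD tertile; "
            f"feasible k <= {oblig_pool.size}"
        )
    order = oblig_pool[np.lexsort((oblig_pool, -means[oblig_pool]))]
    labels.iloc[order[:k]] = "Obligatory"
    return SubnetworkLabels(labels, params)


def split_half_r2(means_a, means_b) -> float:
    """Squared Pearson correlation of per-ROI mean responses across halves."""
    a = np.asarray(means_a, dtype=float).ravel()
    b = np.asarray(means_b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ConfigError("need equal-length vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ConfigError("constant profile has undefined correlation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def split_half_means(
    table: pd.DataFrame, seed: int,
    id_cols: tuple[str, ...] = ("fid", "iid", "site", "sex"),
) -> tuple[pd.Series, pd.Series]:
    """Random seeded split of a phenotype table; per-ROI means of each half."""
    rng = np.random.default_rng(seed)
    n = len(table)
    perm = rng.permutation(n)
    half = n // 2
    pheno_cols = [c for c in table.columns if c not in id_cols]
    a = table.iloc[perm[:half]][pheno_cols].mean()
    b = table.iloc[perm[half:]][pheno_cols].mean()
    return a, b
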