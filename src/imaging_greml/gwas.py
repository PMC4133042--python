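"""Per-SNP association scans (plain OLS, as in array-era GWAS practice).

Each SNP dosage is tested against the phenotype with ordinary least squares
adjusting for covariates (sex and the top genetic PCs, when supplied), via
the Frisch-Waugh projection: phenotype and dosages are residualized on the
covariates and the per-SNP slope is the simple regression of the residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .exceptions import ConfigError
from .genotypes import GenotypeMatrix


def gwas_scan(
    g: GenotypeMatrix, y, covariates=None
) -> pd.DataFrame:
    """OLS association of each SNP with the phenotype.

    Missing dosages are mean-imputed for the scan.  Monomorphic SNPs get
    effect 0, p = 1 and a ``flagged`` mark.  Returns a frame with columns
    snp, beta, se, t, p, flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if g.n != n:
        raise ConfigError("phenotype length does not match genotype rows")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            raise ConfigError("covariate rows must match phenotype length")
        if not np.any(np.ptp(C, axis=0) == 0):
            C = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ConfigError("covariate matrix is rank deficient")

    X = g.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)

    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    dof = n - C.shape[1] - 1
    if dof <= 0:
        raise ConfigError("not enough samples for the covariate set")

    mono = sxx <= 1e-12 * n
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = np.where(mono, 0.0, sxy / sxx_safe)
    rss = y_r @ y_r - beta**2 * sxx_safe
    sigma2 = np.clip(rss, 0, None) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(mono | (se == 0), 0.0, beta / se)
    pval = np.where(mono, 1.0, 2.0 * t_dist.sf(np.abs(tval), dof))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "snp": g.snp_meta["id"].to_numpy(),
            "beta": beta,
            "se": np.where(mono, np.nan, se),
            "t": tval,
            "p": pval,
            "flagged": mono,
        }
    )


def snp_count_by_threshold(
    gwas: pd.DataFrame,
    thresholds=(0.001, 0.01, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
) -> pd.Series:
    """Number of SNPs with p strictly below each threshold."""
    p = gwas["p"].to_numpy()
    counts = {t: int((p < t).sum()) for t in thresholds}
    return pd.Series(counts, name="n_snps").rename_axis("threshold")
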