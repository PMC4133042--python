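"""Variance-component estimation against a genomic relationship matrix.

Implements restricted maximum likelihood for the mixed model

    y = X beta + g + e,   var(y) = A * VG + I * VE,

where A is the GRM, by average-information (AI) REML with a single EM warm-up
step, and the boundary likelihood-ratio test of VG = 0 whose null is the
50:50 mixture of a point mass at zero and chi-square(1) — hence the
alpha = 0.05 critical value 2.7055, the 0.90 quantile of chi-square(1).

The bivariate model stacks two traits and estimates six components
(VG1, VG2, covG, VE1, VE2, covE); the genetic correlation is
rG = covG / sqrt(VG1 * VG2) with a delta-method standard error.

Model classes follow the statsmodels convention: construct from data, call
``fit()``, receive a results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, norm

from .exceptions import ConfigError, OptimizerError
from .grm import GRM

_VAR_FLOOR_FRAC = 1e-6  # constrained components truncated at this * Vp


# ---------------------------------------------------------------------------
# generic multi-component AI-REML engine
# ---------------------------------------------------------------------------

@dataclass
class _RemlState:
    theta: np.ndarray
    loglike: float
    grad: np.ndarray
    ai: np.ndarray
    Py: np.ndarray


def _reml_eval(y, X, comps, theta):
    """Restricted log-likelihood, gradient and AI matrix at theta.

    Returns None if V(theta) is not positive definite.
    """
    n, p = X.shape
    V = np.zeros((n, n))
    for t, G in zip(theta, comps):
        V += t * G
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    except ValueError:
        return None
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vinv - ViX @ XtViX_inv @ ViX.T
    Py = P @ y
    yPy = float(y @ Py)
    loglike = -0.5 * (logdet_V + logdet_X + yPy)

    k = len(comps)
    GPy = [G @ Py for G in comps]
    grad = np.empty(k)
    for i, G in enumerate(comps):
        tr_PG = float(np.sum(P * G))  # G symmetric
        grad[i] = -0.5 * (tr_PG - float(Py @ GPy[i]))
    PGPy = [P @ v for v in GPy]
    ai = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(GPy[i] @ PGPy[j])
    return _RemlState(np.asarray(theta, float), loglike, grad, ai, Py)


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    comps: list[np.ndarray],
    var_idx: list[int] | None = None,
    start: np.ndarray | None = None,
    constrain: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Maximize the restricted likelihood of var(y) = sum_k theta_k comps[k].

    ``var_idx`` marks the components that are variances (kept non-negative
    in constrained mode); the rest are covariances and free in sign.  One
    EM warm-up step precedes the AI updates; an AI step that fails to
    increase the likelihood is halved and ultimately replaced by an EM step.
    A singular AI matrix at the solution marks the fit non-converged (the
    components are not separately identifiable there).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ConfigError("X rows must match the phenotype length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError("covariate matrix is rank deficient")
    k = len(comps)
    var_idx = list(range(k)) if var_idx is None else list(var_idx)
    vp = float(np.var(y, ddof=1))
    floor = _VAR_FLOOR_FRAC * vp

    if start is None:
        start = np.zeros(k)
        for i in var_idx:
            start[i] = vp / len(var_idx)
    theta = np.asarray(start, dtype=float).copy()

    def clamp(th):
        th = th.copy()
        if constrain:
            for i in var_idx:
                th[i] = max(th[i], floor)
        return th

    theta = clamp(theta)
    state = _reml_eval(y, X, comps, theta)
    if state is None:
        raise OptimizerError("initial variance structure not positive definite")

    # one EM warm-up step (variance components only; robust far from optimum)
    em = _em_step(theta, var_idx, state, n)
    em = clamp(em)
    cand = _reml_eval(y, X, comps, em)
    if cand is not None and cand.loglike >= state.loglike - 1e-10:
        theta, state = em, cand

    converged = False
    ai_singular = False
    n_iter = 1
    for it in range(2, max_iter + 1):
        n_iter = it
        # active-set handling: a constrained variance pinned at its floor
        # with a downhill gradient is held fixed, and the AI system is
        # solved for the free components only
        fixed = [
            i for i in var_idx
            if constrain and state.theta[i] <= floor * (1 + 1e-9)
            and state.grad[i] < 0
        ]
        free_idx = [i for i in range(k) if i not in fixed]
        if len(free_idx) == 0:
            converged = True
            break
        ai = state.ai[np.ix_(free_idx, free_idx)]
        grad_f = state.grad[free_idx]
        ai_singular = (
            not np.all(np.isfinite(ai))
            or np.linalg.cond(ai) > 1e10
        )
        delta = None
        if ai_singular:
            # minimum-norm ascent in the identifiable subspace; lets the
            # optimizer track a degenerate ridge (e.g. duplicated traits)
            delta_f = np.linalg.pinv(ai, rcond=1e-12) @ grad_f
            if np.all(np.isfinite(delta_f)):
                delta = np.zeros(k)
                delta[free_idx] = delta_f
        else:
            try:
                delta = np.zeros(k)
                delta[free_idx] = np.linalg.solve(ai, grad_f)
            except np.linalg.LinAlgError:
                ai_singular = True
                delta = None

        scale = tol * max(1.0, abs(state.loglike))
        accepted = None
        done = False
        if delta is not None:
            step = 1.0
            for _ in range(20):
                cand_theta = clamp(state.theta + step * delta)
                cand = _reml_eval(y, X, comps, cand_theta)
                if cand is not None:
                    change = cand.loglike - state.loglike
                    if abs(change) <= scale and step >= 0.5:
                        # the (near-)full AI step no longer moves the
                        # likelihood: converged
                        state = cand
                        converged = not ai_singular
                        done = True
                        break
                    if change >= -1e-10:
                        accepted = cand
                        break
                step *= 0.5
        if done:
            break
        if accepted is None:
            em_theta = clamp(_em_step(state.theta, var_idx, state, n))
            cand = _reml_eval(y, X, comps, em_theta)
            if cand is not None and cand.loglike >= state.loglike - 1e-10:
                accepted = cand
        if accepted is None:
            break  # no acceptable move left; flagged non-converged

        change = abs(accepted.loglike - state.loglike)
        state = accepted
        if change <= scale and ai_singular:
            break  # stalled on a degenerate ridge; flagged non-converged

    constrained_active = constrain and any(
        state.theta[i] <= floor * (1 + 1e-9) for i in var_idx
    )
    cov = _safe_inv(state.ai)
    return {
        "theta": state.theta,
        "loglike": state.loglike,
        "grad": state.grad,
        "ai": state.ai,
        "cov": cov,
        "n_iter": n_iter,
        "converged": converged,
        "constrained": constrained_active,
        "ai_singular": ai_singular,
        "vp_sample": vp,
        "n": n,
        "p": X.shape[1],
    }


def _em_step(theta, var_idx, state, n):
    """Classic EM-REML update theta_i + theta_i^2 (y'P G P y - tr(P G)) / n.

    Since grad_i = -0.5 (tr(P G_i) - y'P G_i P y), the bracket equals
    2 grad_i, so the update is theta_i + 2 theta_i^2 grad_i / n.
    """
    out = theta.copy()
    for i in var_idx:
        out[i] = theta[i] + 2.0 * theta[i] ** 2 * state.grad[i] / n
    return out


def _safe_inv(a):
    try:
        if np.linalg.cond(a) < 1e12:
            return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(a)


# ---------------------------------------------------------------------------
# univariate model
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    """Boundary LRT of VG = 0 against the 0.5*chi2_0 + 0.5*chi2_1 mixture."""

    statistic: float
    df: int
    p_value: float


def lrt_critical_value(alpha: float = 0.05) -> float:
    """Critical value of the mixture null at level alpha (2.7055 at 0.05)."""
    return float(chi2.ppf(1.0 - 2.0 * alpha, 1))


def lrt_vg(full_loglike: float, null_loglike: float,
           tol: float = 0.01) -> LrtResult:
    """Likelihood-ratio test of the genetic variance component.

    The statistic is clamped at zero; under the boundary null its
    distribution is the 50:50 point-mass/chi-square(1) mixture, so
    p = 0.5 * P(chi2_1 >= stat) for a positive statistic and 1 at zero.
    """
    diff = 2.0 * (full_loglike - null_loglike)
    if diff < -tol:
        raise OptimizerError(
            f"full-model log-likelihood below the null by {-diff / 2:.3g}; "
            "optimizer fault"
        )
    stat = max(0.0, diff)
    if stat == 0.0:
        p = 1.0
    else:
        p = 0.5 * float(chi2.sf(stat, 1))
    return LrtResult(statistic=stat, df=1, p_value=p)


class GREML:
    """GREML variance-component model for one phenotype against a GRM.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Phenotype vector, aligned with ``grm.sample_ids``.
    exog : array-like, shape (n, p), optional
        Fixed-effect design matrix.  An intercept column is appended if no
        (near-)constant column is present.
    grm : GRM
        Genomic relationship matrix for the same samples.
    constrain : bool
        Keep VG and VE non-negative (truncated at 1e-6 * Vp), as GCTA does
        by default.
    """

    def __init__(self, endog, exog=None, *, grm: GRM, constrain: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        if grm.n != y.size:
            raise ConfigError("GRM size does not match phenotype length")
        if exog is None:
            X = np.ones((y.size, 1))
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if X.shape[0] != y.size:
                raise ConfigError("exog rows must match phenotype length")
            has_const = np.any(np.ptp(X, axis=0) == 0)
            if not has_const:
                X = np.column_stack([np.ones(y.size), X])
        mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if not mask.all():
            y = y[mask]
            X = X[mask]
            grm = grm.take(np.flatnonzero(mask))
        self.endog = y
        self.exog = X
        self.grm = grm
        self.constrain = constrain
        self._null_loglike: float | None = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, pheno: str,
                       covars: list[str] | None = None, *, grm: GRM,
                       constrain: bool = True) -> "GREML":
        covars = covars or []
        X = data[covars].to_numpy(dtype=float) if covars else None
        return cls(data[pheno].to_numpy(dtype=float), X, grm=grm,
                   constrain=constrain)

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "GREMLResults":
        comps = [self.grm.values, np.eye(len(self.endog))]
        res = ai_reml(
            self.endog, self.exog, comps, var_idx=[0, 1],
            constrain=self.constrain, max_iter=max_iter, tol=tol,
        )
        return GREMLResults(self, res)

    def null_loglike(self) -> float:
        """Restricted log-likelihood of the fixed-effects-only model.

        Closed form: with V = sigma^2 I the REML maximum sits at
        sigma^2 = RSS / (n - p), using the same likelihood constant
        convention as the iterative fit.
        """
        if self._null_loglike is None:
            y, X = self.endog, self.exog
            n, p = X.shape
            Q, _ = np.linalg.qr(X)
            resid = y - Q @ (Q.T @ y)
            rss = float(resid @ resid)
            sigma2 = rss / (n - p)
            _, logdet_xtx = np.linalg.slogdet(X.T @ X)
            self._null_loglike = float(
                -0.5 * ((n - p) * np.log(sigma2) + logdet_xtx + (n - p))
            )
        return self._null_loglike


class GREMLResults:
    """Estimates, standard errors and diagnostics of a univariate GREML fit."""

    def __init__(self, model: GREML, raw: dict):
        self.model = model
        self._raw = raw
        self.vg, self.ve = (float(t) for t in raw["theta"])
        self.vp = self.vg + self.ve
        self.ratio = self.vg / self.vp if self.vp > 0 else np.nan
        self.loglike = float(raw["loglike"])
        self.n_iter = int(raw["n_iter"])
        self.converged = bool(raw["converged"])
        self.constrained = bool(raw["constrained"])
        self.cov_params = raw["cov"]
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        self.se_vg, self.se_ve = (float(s) for s in se)
        # delta method for VG / (VG + VE)
        if self.vp > 0:
            grad = np.array([self.ve, -self.vg]) / self.vp**2
            var_ratio = float(grad @ self.cov_params @ grad)
            self.se_ratio = float(np.sqrt(max(var_ratio, 0.0)))
        else:
            self.se_ratio = np.nan

    @property
    def n(self) -> int:
        return int(self._raw["n"])

    def lrt(self) -> LrtResult:
        """Boundary LRT of VG = 0 against the fixed-effects-only null."""
        return lrt_vg(self.loglike, self.model.null_loglike())

    def summary(self) -> str:
        t = self.lrt()
        lines = [
            "GREML variance components (AI-REML)",
            "=" * 44,
            f"n samples          {self.n:>12d}",
            f"VG                 {self.vg:>12.4f}  (SE {self.se_vg:.4f})",
            f"VE                 {self.ve:>12.4f}  (SE {self.se_ve:.4f})",
            f"Vp                 {self.vp:>12.4f}",
            f"VG/Vp              {self.ratio:>12.4f}  (SE {self.se_ratio:.4f})",
            f"logL (REML)        {self.loglike:>12.4f}",
            f"LRT (VG=0)         {t.statistic:>12.4f}  p = {t.p_value:.4g}",
            f"iterations         {self.n_iter:>12d}",
            f"converged          {str(self.converged):>12s}",
            f"constrained        {str(self.constrained):>12s}",
        ]
        return "\n".join(lines)


def reml_univariate(y, X, grm: GRM, constrain: bool = True) -> GREMLResults:
    """Functional wrapper: fit the univariate GREML model and return results."""
    return GREML(y, X, grm=grm, constrain=constrain).fit()


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------

class BivariateGREML:
    """Bivariate GREML: genetic and environmental (co)variances of two traits.

    The stacked model for y = (y1', y2')' has covariance

        V = [[A VG1 + I VE1,     A covG + I covE],
             [A covG + I covE,   A VG2 + I VE2  ]]

    with trait-specific fixed effects (the same covariate matrix applied to
    each trait, block-diagonally).  Samples missing either trait are dropped
    pairwise-complete, with the GRM re-aligned.
    """

    def __init__(self, endog1, endog2, exog=None, *, grm: GRM,
                 constrain: bool = True):
        y1 = np.asarray(endog1, dtype=float).ravel()
        y2 = np.asarray(endog2, dtype=float).ravel()
        if y1.size != y2.size or y1.size != grm.n:
            raise ConfigError("traits and GRM must cover the same samples")
        if exog is None:
            X = np.ones((y1.size, 1))
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if np.all(np.ptp(X, axis=0) != 0):
                X = np.column_stack([np.ones(y1.size), X])
        mask = np.isfinite(y1) & np.isfinite(y2) & np.all(np.isfinite(X), axis=1)
        idx = np.flatnonzero(mask)
        self.y1, self.y2, self.X = y1[idx], y2[idx], X[idx]
        self.grm = grm.take(idx)
        self.constrain = constrain

    def fit(self, max_iter: int = 100, tol: float = 1e-8
            ) -> "BivariateGREMLResults":
        n = self.y1.size
        # perfectly collinear traits make the 6-component model degenerate:
        # the likelihood supremum sits at the singular boundary rG = +/-1,
        # so report that limit directly instead of chasing it numerically
        r12 = np.corrcoef(self.y1, self.y2)[0, 1]
        if abs(r12) > 1.0 - 1e-12:
            warnings.warn(
                "traits are perfectly correlated; bivariate model is "
                "degenerate, reporting the boundary solution rG = +/-1",
                RuntimeWarning, stacklevel=2,
            )
            sgn = float(np.sign(r12))
            uni = GREML(self.y1, self.X, grm=self.grm,
                        constrain=self.constrain).fit()
            raw = dict(uni._raw)
            raw["theta"] = np.array([
                uni.vg, uni.vg, sgn * uni.vg, uni.ve, uni.ve, sgn * uni.ve,
            ])
            raw["cov"] = np.zeros((6, 6))
            raw["converged"] = uni.converged
            return BivariateGREMLResults(self, raw)
        A = self.grm.values
        I = np.eye(n)
        Z = np.zeros((n, n))

        def block(m11, m12, m22):
            return np.block([[m11, m12], [m12, m22]])

        comps = [
            block(A, Z, Z),   # VG1
            block(Z, Z, A),   # VG2
            block(Z, A, Z),   # covG
            block(I, Z, Z),   # VE1
            block(Z, Z, I),   # VE2
            block(Z, I, Z),   # covE
        ]
        y = np.concatenate([self.y1, self.y2])
        Xs = np.kron(np.eye(2), self.X)
        vp1 = np.var(self.y1, ddof=1)
        vp2 = np.var(self.y2, ddof=1)
        c0 = 0.25 * np.cov(self.y1, self.y2, ddof=1)[0, 1]
        start = np.array([vp1 / 2, vp2 / 2, c0, vp1 / 2, vp2 / 2, c0])
        res = ai_reml(
            y, Xs, comps, var_idx=[0, 1, 3, 4], start=start,
            constrain=self.constrain, max_iter=max_iter, tol=tol,
        )
        return BivariateGREMLResults(self, res)


class BivariateGREMLResults:
    """Genetic correlation and (co)variance components of two traits."""

    _names = ("vg1", "vg2", "cov_g", "ve1", "ve2", "cov_e")

    def __init__(self, model: BivariateGREML, raw: dict):
        self.model = model
        self._raw = raw
        (self.vg1, self.vg2, self.cov_g,
         self.ve1, self.ve2, self.cov_e) = (float(t) for t in raw["theta"])
        self.loglike = float(raw["loglike"])
        self.converged = bool(raw["converged"])
        self.constrained = bool(raw["constrained"])
        self.n_iter = int(raw["n_iter"])
        self.cov_params = raw["cov"]

        floor = _VAR_FLOOR_FRAC * raw["vp_sample"] * 10
        self.unstable = self.vg1 <= floor or self.vg2 <= floor
        if self.vg1 > 0 and self.vg2 > 0:
            denom = np.sqrt(self.vg1 * self.vg2)
            self.rg = float(np.clip(self.cov_g / denom, -1.0, 1.0))
            g = np.zeros(6)
            g[0] = -0.5 * self.cov_g / (denom * self.vg1)
            g[1] = -0.5 * self.cov_g / (denom * self.vg2)
            g[2] = 1.0 / denom
            var_rg = float(g @ self.cov_params @ g)
            self.se_rg = float(np.sqrt(max(var_rg, 0.0)))
        else:
            self.rg, self.se_rg = np.nan, np.nan
        se_covg = float(np.sqrt(max(self.cov_params[2, 2], 0.0)))
        self.se_cov_g = se_covg
        if se_covg > 0:
            z = self.cov_g / se_covg
            self.p_cov_g = float(2.0 * norm.sf(abs(z)))
        else:
            self.p_cov_g = np.nan
        if self.unstable:
            warnings.warn(
                "a genetic variance sits at its boundary; rG is unstable",
                RuntimeWarning, stacklevel=2,
            )

    def summary(self) -> str:
        lines = [
            "Bivariate GREML (AI-REML, 6 components)",
            "=" * 46,
            f"VG1 {self.vg1:10.4f}   VG2 {self.vg2:10.4f}   covG {self.cov_g:10.4f}",
            f"VE1 {self.ve1:10.4f}   VE2 {self.ve2:10.4f}   covE {self.cov_e:10.4f}",
            f"rG  {self.rg:10.4f}   (SE {self.se_rg:.4f})   "
            f"Wald p(covG=0) = {self.p_cov_g:.4g}",
            f"logL {self.loglike:.4f}   iters {self.n_iter}   "
            f"converged {self.converged}   unstable {self.unstable}",
        ]
        return "\n".join(lines)


def reml_bivariate(y1, y2, X, grm: GRM,
                   constrain: bool = True) -> BivariateGREMLResults:
    """Functional wrapper: fit the bivariate GREML model and return results."""
    return BivariateGREML(y1, y2, X, grm=grm, constrain=constrain).fit()
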