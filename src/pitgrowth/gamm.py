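"""Nonlinear trajectory modelling for densely sampled longitudinal series.

The model for a person-centred feature :math:`y_{ij}` of subject *i* at
gestational week :math:`t_{ij}` is

.. math::

    y_{ij} = f(t_{ij}) + b_i + e_{ij},\qquad
    b_i \sim N(0, \sigma_b^2),\qquad
    \mathrm{cov}(e_{ij}, e_{ik}) = \sigma_e^2\,\rho^{|t_{ij}-t_{ik}|},

i.e. a smooth trajectory shared across subjects, Gaussian subject
intercepts, and continuous-time AR(1) residual correlation with
per-week correlation :math:`\rho`.  The smooth is a cubic B-spline with
``k`` basis functions (default 10) and an integrated-squared-second-
derivative penalty, whose null space is exactly the constant-plus-line
family, so infinite smoothing collapses the fit onto the generalised
least-squares line.

Estimation profiles the residual scale and maximises the restricted
likelihood jointly over the smoothing parameter, :math:`\rho`, and the
intercept-to-residual variance ratio: for fixed values of those three,
whitening by the Cholesky factor of the marginal working covariance
makes the penalised solution closed form.  The outer optimisation is a
deterministic derivative-free search from three fixed starting points.

Inference utilities follow the same playbook as mainstream additive-
model software: Bayesian coefficient covariance for pointwise bands,
exact B-spline differentiation for the first-derivative curve, runs
where the 95% derivative band excludes zero as "periods of significant
change", and sign changes of the fitted derivative as local extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from scipy.interpolate import BSpline


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------


def car1_correlation(
    times: np.ndarray, rho: float, subjects: np.ndarray | None = None
) -> np.ndarray:
    """Continuous-AR(1) correlation matrix: entry (j,k) = rho**|t_j - t_k|.

    With ``subjects`` given, correlation is block-diagonal across
    subjects (zero between different subjects).  ``rho = 0`` yields the
    identity (0**0 = 1 on the diagonal by convention).
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    lag = np.abs(t[:, None] - t[None, :])
    if rho == 0.0:
        corr = np.where(lag == 0.0, 1.0, 0.0)
    else:
        corr = rho ** lag
    if subjects is not None:
        s = np.asarray(subjects)
        corr = corr * (s[:, None] == s[None, :])
    return corr


# ---------------------------------------------------------------------------
# B-spline basis and curvature penalty
# ---------------------------------------------------------------------------


@dataclass
class SplineBasis:
    """Cubic B-spline basis with k functions on quantile-placed knots."""

    knots: np.ndarray  # full knot vector, length k + 4
    k: int
    degree: int = 3

    @classmethod
    def from_times(cls, times: np.ndarray, k: int = 10) -> "SplineBasis":
        t = np.unique(np.asarray(times, dtype=float))
        if t.size < 2:
            raise ValueError("singular design: need at least two distinct times")
        lo, hi = t[0], t[-1]
        n_interior = k - 4
        if n_interior < 0:
            raise ValueError("k must be >= 4 for a cubic basis")
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(t, qs)
        else:
            interior = np.array([])
        knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        return cls(knots=knots, k=k)

    def design(self, x: np.ndarray, deriv: int = 0) -> np.ndarray:
        """(len(x), k) design matrix of the basis (or its derivative)."""
        spl = BSpline(self.knots, np.eye(self.k), self.degree, extrapolate=True)
        if deriv:
            spl = spl.derivative(deriv)
        return np.asarray(spl(np.asarray(x, dtype=float)))

    def curvature_penalty(self) -> np.ndarray:
        """S = integral of B''(t) B''(t)^T dt over the knot range.

        The second derivative of a cubic spline is piecewise linear, so
        two-point Gauss-Legendre per knot span integrates exactly.
        """
        uniq = np.unique(self.knots)
        gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        S = np.zeros((self.k, self.k))
        for a, b in zip(uniq[:-1], uniq[1:]):
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            pts = mid + half * gauss_x
            D2 = self.design(pts, deriv=2)
            S += half * (D2.T @ D2)
        return S


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class SmoothFit:
    """Fitted trajectory model and everything inference needs."""

    basis: SplineBasis
    beta: np.ndarray
    lam: float
    rho: float
    sigma2_e: float
    sigma2_b: float
    cov_beta: np.ndarray
    edf: float                 # smooth edf excluding the constant
    edf_model: float           # smooth + shrunk random-intercept edf
    adj_r2: float
    f_stat: float
    f_pvalue: float
    aic: float
    reml: float                # minimised -2 restricted log-likelihood
    reml_at_starts: tuple[float, ...]
    converged: bool
    n_obs: int
    weeks: np.ndarray
    response: np.ndarray
    subjects: np.ndarray
    subject_levels: np.ndarray
    blups: np.ndarray          # one shrunk intercept per subject level
    fitted_fixed: np.ndarray
    fitted_full: np.ndarray
    response_column: str = ""

    def predict(self, weeks: np.ndarray) -> np.ndarray:
        """Population (fixed-effect) prediction of the smooth."""
        return self.basis.design(np.asarray(weeks, dtype=float)) @ self.beta

    @property
    def residuals(self) -> np.ndarray:
        return self.response - self.fitted_full


@dataclass
class DerivativeBand:
    """First-derivative curve with pointwise 95% bounds and summaries."""

    grid: np.ndarray
    deriv: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant_intervals: list[tuple[float, float]]
    extrema: list[dict]  # {"week", "value_sd", "type"}


@dataclass
class WindowFit:
    """Random-intercept linear fit restricted to a week window."""

    lo_week: float
    hi_week: float
    slope: float
    slope_se: float
    pvalue: float
    intercept: float
    subject_intercepts: dict[str, float]
    n_obs: int


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

_NULL_DIM = 2  # constant + line: null space of the curvature penalty

# fixed multi-start points in (log lambda, logit rho, log variance-ratio)
_REML_STARTS = (
    (0.0, special.logit(0.30), 0.0),
    (6.0, special.logit(0.05), -2.0),
    (-3.0, special.logit(0.60), 1.0),
)


def _working_cov(weeks, subj_codes, n_subj, rho, gamma):
    """W = blockdiag_i [ CAR1_i(rho) + gamma * ones ] as a dense matrix."""
    n = len(weeks)
    W = np.zeros((n, n))
    for i in range(n_subj):
        sel = np.flatnonzero(subj_codes == i)
        C = car1_correlation(weeks[sel], rho)
        W[np.ix_(sel, sel)] = C + gamma
    return W


class _REMLProblem:
    def __init__(self, y, B, S, weeks, subj_codes, n_subj):
        self.y = y
        self.B = B
        self.S = S
        self.weeks = weeks
        self.subj_codes = subj_codes
        self.n_subj = n_subj
        self.n = len(y)
        self.k = B.shape[1]
        eigS = np.linalg.eigvalsh(S)
        self.log_eigS_pos = np.log(eigS[eigS > eigS.max() * 1e-10]).sum()

    def theta_to_params(self, theta):
        lam = float(np.exp(np.clip(theta[0], -25, 25)))
        rho = float(special.expit(np.clip(theta[1], -25, 25)))
        gamma = float(np.exp(np.clip(theta[2], -25, 25)))
        return lam, rho, gamma

    def neg2_reml(self, theta):
        lam, rho, gamma = self.theta_to_params(theta)
        try:
            return self._neg2_reml_at(lam, rho, gamma)[0]
        except np.linalg.LinAlgError:
            return 1e12

    def _neg2_reml_at(self, lam, rho, gamma):
        W = _working_cov(self.weeks, self.subj_codes, self.n_subj, rho, gamma)
        L = np.linalg.cholesky(W)
        Xt = linalg.solve_triangular(L, self.B, lower=True)
        yt = linalg.solve_triangular(L, self.y, lower=True)
        M = Xt.T @ Xt + lam * self.S
        cf = linalg.cho_factor(M, lower=True)
        beta = linalg.cho_solve(cf, Xt.T @ yt)
        resid = yt - Xt @ beta
        rss_pen = float(resid @ resid + lam * beta @ self.S @ beta)
        dof = self.n - _NULL_DIM
        sigma2 = rss_pen / dof
        logdet_M = 2.0 * np.log(np.diag(cf[0])).sum()
        logdet_W = 2.0 * np.log(np.diag(L)).sum()
        logdet_lamS = (self.k - _NULL_DIM) * np.log(lam) + self.log_eigS_pos
        neg2 = (
            dof * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + logdet_W
            + logdet_M
            - logdet_lamS
        )
        return neg2, dict(
            W=W, L=L, Xt=Xt, yt=yt, M=M, cf=cf, beta=beta, sigma2=sigma2
        )


def fit_gamm(
    table: pd.DataFrame,
    response_column: str,
    k: int = 10,
    weeks_column: str = "weeks",
    subject_column: str = "subject_id",
    fixed_lambda: float | None = None,
    fixed_rho: float | None = None,
    fixed_gamma: float | None = None,
) -> SmoothFit:
    """Fit the penalized-spline mixed model to one feature column.

    ``fixed_*`` pin individual variance/smoothing parameters instead of
    estimating them (used for limit checks and diagnostics); free
    parameters are estimated by REML with three fixed starting points.
    Exact criterion ties across starts resolve to the smallest lambda.
    """
    data = table.dropna(subset=[response_column, weeks_column]).copy()
    subj_levels, subj_codes = np.unique(data[subject_column], return_inverse=True)
    n_subj = len(subj_levels)
    y = data[response_column].to_numpy(dtype=float)
    weeks = data[weeks_column].to_numpy(dtype=float)
    n = len(y)
    if n_subj < 2:
        raise ValueError("need >= 2 subjects to separate trajectory and intercepts")
    if n < 8:
        raise ValueError("need >= 8 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if np.unique(weeks).size < 2:
        raise ValueError("singular design: all observation times equal")

    basis = SplineBasis.from_times(weeks, k=k)
    B = basis.design(weeks)
    S = basis.curvature_penalty()
    prob = _REMLProblem(y, B, S, weeks, subj_codes, n_subj)

    fixed = (fixed_lambda, fixed_rho, fixed_gamma)
    free_idx = [i for i, v in enumerate(fixed) if v is None]

    def pack(theta_free):
        theta = np.empty(3)
        j = 0
        for i in range(3):
            if fixed[i] is None:
                theta[i] = theta_free[j]
                j += 1
            elif i == 0:
                theta[i] = np.log(max(fixed[0], 1e-12))
            elif i == 1:
                theta[i] = special.logit(np.clip(fixed[1], 1e-12, 1 - 1e-12))
            else:
                theta[i] = np.log(max(fixed[2], 1e-12))
        return theta

    converged = True
    start_values = []
    if free_idx:
        best = None
        for start in _REML_STARTS:
            x0 = np.array([start[i] for i in free_idx])
            start_values.append(prob.neg2_reml(pack(x0)))
            res = optimize.minimize(
                lambda tf: prob.neg2_reml(pack(tf)),
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
            )
            lam_here = prob.theta_to_params(pack(res.x))[0]
            key = (res.fun, lam_here)
            if (
                best is None
                or res.fun < best[0] - 1e-8
                or (abs(res.fun - best[0]) <= 1e-8 and lam_here < best[1])
            ):
                best = (res.fun, lam_here, res)
        res = best[2]
        if not res.success:
            converged = False
            warnings.warn(
                "REML optimisation did not report convergence; returning best "
                "point found", stacklevel=2,
            )
        theta = pack(res.x)
    else:
        theta = pack(np.array([]))
        start_values = [prob.neg2_reml(theta)]

    lam, rho, gamma = prob.theta_to_params(theta)
    if fixed_lambda is not None:
        lam = fixed_lambda
    if fixed_rho is not None:
        rho = fixed_rho
    if fixed_gamma is not None:
        gamma = fixed_gamma
    reml_val, aux = prob._neg2_reml_at(lam, rho, gamma)

    beta = aux["beta"]
    sigma2_e = aux["sigma2"]
    sigma2_b = gamma * sigma2_e
    Minv = linalg.cho_solve(aux["cf"], np.eye(prob.k))
    cov_beta = sigma2_e * Minv
    XtX = aux["Xt"].T @ aux["Xt"]
    edf_total = float(np.trace(Minv @ XtX))
    edf = edf_total - 1.0

    fitted_fixed = B @ beta
    resid_fixed = y - fitted_fixed
    blups = np.zeros(n_subj)
    edf_ranef = 0.0
    for i in range(n_subj):
        sel = np.flatnonzero(subj_codes == i)
        C = car1_correlation(weeks[sel], rho) + gamma
        Cinv_r = np.linalg.solve(C, resid_fixed[sel])
        blups[i] = gamma * Cinv_r.sum()
        edf_ranef += gamma * np.trace(
            np.linalg.solve(C, np.full((len(sel), len(sel)), 1.0))
        )
    fitted_full = fitted_fixed + blups[subj_codes]
    rss = float(np.sum((y - fitted_full) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    edf_model = edf + edf_ranef
    denom = max(n - edf_model - 1.0, 1.0)
    adj_r2 = 1.0 - (rss / denom) / (tss / (n - 1.0)) if tss > 0 else float("nan")

    # Wald-type test of the smooth (approximate): centred fitted values
    # against their Bayesian covariance at rank ~= edf.
    center = np.eye(n) - np.full((n, n), 1.0 / n)
    A = center @ B
    f_c = A @ beta
    V_fc = A @ cov_beta @ A.T
    r_rank = int(np.clip(round(edf), 1, prob.k - 1))
    evals, evecs = np.linalg.eigh(V_fc)
    order = np.argsort(evals)[::-1][:r_rank]
    proj = evecs[:, order].T @ f_c
    chi2 = float(np.sum(proj**2 / np.maximum(evals[order], 1e-300)))
    f_stat = chi2 / r_rank
    f_pvalue = float(stats.f.sf(f_stat, r_rank, max(denom, 1.0)))

    # marginal Gaussian log-likelihood at the REML estimates
    V = sigma2_e * aux["W"]
    Lv = np.linalg.cholesky(V)
    wres = linalg.solve_triangular(Lv, resid_fixed, lower=True)
    loglik = -0.5 * (
        n * np.log(2.0 * np.pi) + 2.0 * np.log(np.diag(Lv)).sum() + wres @ wres
    )
    aic = float(-2.0 * loglik + 2.0 * (edf_model + 1.0 + 3.0))

    return SmoothFit(
        basis=basis,
        beta=beta,
        lam=lam,
        rho=rho,
        sigma2_e=sigma2_e,
        sigma2_b=sigma2_b,
        cov_beta=cov_beta,
        edf=edf,
        edf_model=edf_model,
        adj_r2=adj_r2,
        f_stat=f_stat,
        f_pvalue=f_pvalue,
        aic=aic,
        reml=float(reml_val),
        reml_at_starts=tuple(start_values),
        converged=converged,
        n_obs=n,
        weeks=weeks,
        response=y,
        subjects=data[subject_column].to_numpy(),
        subject_levels=subj_levels,
        blups=blups,
        fitted_fixed=fitted_fixed,
        fitted_full=fitted_full,
        response_column=response_column,
    )


# ---------------------------------------------------------------------------
# derivative-based localisation of growth phases
# ---------------------------------------------------------------------------


def derivative_inference(
    fit: SmoothFit, grid_step: float = 0.1, level: float = 0.95
) -> DerivativeBand:
    """First-derivative curve, pointwise band, change intervals, extrema.

    The derivative comes from exact differentiation of the B-spline
    basis; "significant change" intervals are maximal grid runs where
    the pointwise band excludes zero; extrema are sign changes of the
    fitted derivative (week located by linear interpolation).
    """
    if not fit.converged:
        raise ValueError("derivative inference requires a converged fit")
    lo_w, hi_w = fit.weeks.min(), fit.weeks.max()
    grid = np.arange(lo_w, hi_w + grid_step / 2, grid_step)
    D = fit.basis.design(grid, deriv=1)
    fprime = D @ fit.beta
    var = np.einsum("ij,jk,ik->i", D, fit.cov_beta, D)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.maximum(var, 0.0))
    lower, upper = fprime - z * se, fprime + z * se

    sig = (lower > 0.0) | (upper < 0.0)
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            intervals.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(grid[-1])))

    extrema: list[dict] = []
    for i in range(len(grid) - 1):
        a, b = fprime[i], fprime[i + 1]
        if a == 0.0 or np.sign(a) == np.sign(b):
            continue
        w = grid[i] + (grid[i + 1] - grid[i]) * (a / (a - b))
        value = float((fit.basis.design(np.array([w])) @ fit.beta).item())
        extrema.append(
            {
                "week": float(w),
                "value_sd": value,
                "type": "min" if a < 0 else "max",
            }
        )
    return DerivativeBand(
        grid=grid,
        deriv=fprime,
        lower=lower,
        upper=upper,
        significant_intervals=intervals,
        extrema=extrema,
    )


def principal_extrema(band: DerivativeBand) -> dict[str, dict | None]:
    """Deepest minimum and highest maximum of the fitted trajectory."""
    mins = [e for e in band.extrema if e["type"] == "min"]
    maxs = [e for e in band.extrema if e["type"] == "max"]
    return {
        "min": min(mins, key=lambda e: e["value_sd"]) if mins else None,
        "max": max(maxs, key=lambda e: e["value_sd"]) if maxs else None,
    }


# ---------------------------------------------------------------------------
# windowed linear mixed models
# ---------------------------------------------------------------------------

EARLY_WINDOW = (-5.0, 12.0)
LATE_WINDOW = (12.0, 40.0)


def fit_window_lmm(
    table: pd.DataFrame,
    lo_week: float,
    hi_week: float,
    response_column: str = "z_vol_anterior",
    weeks_column: str = "weeks",
    subject_column: str = "subject_id",
) -> WindowFit:
    """Random-intercept line fit on observations with lo <= weeks < hi."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    sel = table[
        (table[weeks_column] >= lo_week) & (table[weeks_column] < hi_week)
    ].copy()
    n_subj = sel[subject_column].nunique()
    if len(sel) < 3 or n_subj < 2:
        raise ValueError(
            f"window [{lo_week}, {hi_week}) has {len(sel)} observations from "
            f"{n_subj} subject(s); need >= 3 from >= 2"
        )
    y = sel[response_column].to_numpy(dtype=float)
    w = sel[weeks_column].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(w), w])

    # degenerate noiseless-shared-line case: a single OLS line explains
    # everything exactly and the mixed model would sit on a variance
    # boundary; return the exact line directly.
    ols_beta, ols_res, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_rss = float(np.sum((y - X @ ols_beta) ** 2))
    scale = float(np.sum(y**2)) + 1e-30
    if ols_rss / scale < 1e-18:
        return WindowFit(
            lo_week=lo_week,
            hi_week=hi_week,
            slope=float(ols_beta[1]),
            slope_se=0.0,
            pvalue=0.0,
            intercept=float(ols_beta[0]),
            subject_intercepts={s: 0.0 for s in sel[subject_column].unique()},
            n_obs=len(sel),
        )

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=sel[subject_column].to_numpy())
        for method in ("lbfgs", "powell", "nm"):
            try:
                result = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if result is None:
        raise RuntimeError("window mixed model failed to converge")
    ranef = {str(k): float(v.iloc[0]) for k, v in result.random_effects.items()}
    return WindowFit(
        lo_week=lo_week,
        hi_week=hi_week,
        slope=float(result.params[1]),
        slope_se=float(result.bse[1]),
        pvalue=float(result.pvalues[1]),
        intercept=float(result.params[0]),
        subject_intercepts=ranef,
        n_obs=len(sel),
    )


# ---------------------------------------------------------------------------
# out-of-sample validation and diagnostics
# ---------------------------------------------------------------------------


def loso_cv(
    table: pd.DataFrame,
    response_column: str,
    k: int = 10,
    weeks_column: str = "weeks",
    subject_column: str = "subject_id",
) -> dict:
    """Leave-one-subject-out predictive R² from fixed effects only.

    Per fold the model is refit without one subject; that subject is
    predicted from the smooth alone (random intercept 0 — legitimate
    because responses are person-centred), and fold R² = 1 - SSE/SST
    with SST around the held-out subject's own mean.
    """
    subjects = table[subject_column].unique()
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs >= 3 subjects")
    per_fold = {}
    for held in subjects:
        train = table[table[subject_column] != held]
        test = table[table[subject_column] == held]
        fit = fit_gamm(
            train, response_column, k=k,
            weeks_column=weeks_column, subject_column=subject_column,
        )
        pred = fit.predict(test[weeks_column].to_numpy(dtype=float))
        y = test[response_column].to_numpy(dtype=float)
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        per_fold[str(held)] = 1.0 - sse / sst if sst > 0 else float("nan")
    return {"per_fold": per_fold, "mean": float(np.mean(list(per_fold.values())))}


def _lag1_autocorr(values: np.ndarray, order: np.ndarray, groups: np.ndarray) -> float:
    """Pearson correlation of time-adjacent within-subject residual pairs."""
    left, right = [], []
    for g in np.unique(groups):
        sel = np.flatnonzero(groups == g)
        sel = sel[np.argsort(order[sel])]
        v = values[sel]
        left.append(v[:-1])
        right.append(v[1:])
    left = np.concatenate(left)
    right = np.concatenate(right)
    if left.size < 3 or left.std() == 0 or right.std() == 0:
        return float("nan")
    return float(np.corrcoef(left, right)[0, 1])


def residual_diagnostics(fit: SmoothFit) -> dict:
    """Residual checks: CAR(1) whitening, normality, per-subject means.

    The whitened lag-1 autocorrelation should sit near zero when the
    estimated CAR(1) structure captures the residual dependence.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    resid = fit.residuals
    raw_ac = _lag1_autocorr(resid, fit.weeks, fit.subjects)
    whitened = np.empty_like(resid)
    for g in fit.subject_levels:
        sel = np.flatnonzero(fit.subjects == g)
        sel = sel[np.argsort(fit.weeks[sel])]
        C = car1_correlation(fit.weeks[sel], fit.rho)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(sel)))
        whitened[sel] = linalg.solve_triangular(L, resid[sel], lower=True)
    white_ac = _lag1_autocorr(whitened, fit.weeks, fit.subjects)
    shapiro_p = float(stats.shapiro(resid).pvalue) if len(resid) >= 3 else float("nan")
    per_subject_mean = {
        str(g): float(resid[fit.subjects == g].mean()) for g in fit.subject_levels
    }
    return {
        "raw_lag1_autocorr": raw_ac,
        "whitened_lag1_autocorr": white_ac,
        "shapiro_pvalue": shapiro_p,
        "per_subject_residual_mean": per_subject_mean,
    }
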