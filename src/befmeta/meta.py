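"""Multilevel weighted random-effects meta-analysis with known sampling variances.

The model for effect sizes y_i (Fisher-z correlations) is

    y_i = x_i' beta + u_{study(i)} [+ w_i] + e_i,
    u_s ~ N(0, tau2),  w_i ~ N(0, sigma2_obs),  e_i ~ N(0, v_i) with v_i known,

i.e. a meta-analytic mixed model with a study-level random intercept, an
optional observation-level component on top of the known sampling variances,
and inverse-variance weighting implied by the marginal covariance

    V = diag(v + sigma2_obs) + tau2 * (block of ones per study).

Variance components are estimated by profiled restricted maximum likelihood
(REML, the default) or ML with a derivative-free bounded search; beta is the
GLS estimate given the components. The block-plus-rank-one structure of V is
exploited (Sherman-Morrison within study blocks) so one likelihood evaluation
is O(n p^2), which keeps the resampling-heavy SEM workflows fast.

Moderator tests are Wald-type chi-square (QM) statistics, confidence intervals
are normal-based, and Egger's regression (standardized effect vs. precision)
provides the funnel-asymmetry diagnostic for publication bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaSpec",
    "MetaFit",
    "EggerResult",
    "fit_meta",
    "wald_qm",
    "grand_means",
    "egger_test",
    "funnel_data",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

try:  # JIT-compiled likelihood kernel; a pure-numpy fallback is kept below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=True)
def _nll_kernel(y, X, v, sidx, n_s, tau2, sig2, reml):  # pragma: no cover
    """Profiled negative log-likelihood via per-study Sherman-Morrison blocks.

    Returns +inf when the profiled system is not positive definite. Numerically
    identical to `_Likelihood.nll` (the numpy path), which is what the final
    reported fit always uses; this kernel only drives the optimizer.
    """
    n, p = X.shape
    S1 = np.zeros(n_s)
    Sy = np.zeros(n_s)
    Sx = np.zeros((n_s, p))
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    yWy = 0.0
    logdet = 0.0
    for i in range(n):
        di = v[i] + sig2
        if di <= 0.0:
            return np.inf
        a = 1.0 / di
        s = sidx[i]
        S1[s] += a
        Sy[s] += y[i] * a
        logdet += np.log(di)
        yWy += y[i] * y[i] * a
        for j in range(p):
            xa = X[i, j] * a
            Sx[s, j] += xa
            XtWy[j] += xa * y[i]
            for k in range(j, p):
                XtWX[j, k] += xa * X[i, k]
    for s in range(n_s):
        g = tau2 / (1.0 + tau2 * S1[s])
        logdet += np.log1p(tau2 * S1[s])
        yWy -= g * Sy[s] * Sy[s]
        for j in range(p):
            gj = g * Sx[s, j]
            XtWy[j] -= gj * Sy[s]
            for k in range(j, p):
                XtWX[j, k] -= gj * Sx[s, k]
    # Cholesky of the (upper-triangular-stored) information matrix
    L = np.zeros((p, p))
    logdetI = 0.0
    for j in range(p):
        acc = XtWX[j, j]
        for k in range(j):
            acc -= L[j, k] * L[j, k]
        if acc <= 0.0:
            return np.inf
        L[j, j] = np.sqrt(acc)
        logdetI += 2.0 * np.log(L[j, j])
        for i in range(j + 1, p):
            acc2 = XtWX[j, i]
            for k in range(j):
                acc2 -= L[i, k] * L[j, k]
            L[i, j] = acc2 / L[j, j]
    # solve L L' beta = XtWy
    z = np.zeros(p)
    for j in range(p):
        acc = XtWy[j]
        for k in range(j):
            acc -= L[j, k] * z[k]
        z[j] = acc / L[j, j]
    beta = np.zeros(p)
    for j in range(p - 1, -1, -1):
        acc = z[j]
        for k in range(j + 1, p):
            acc -= L[k, j] * beta[k]
        beta[j] = acc / L[j, j]
    quad = yWy
    for j in range(p):
        quad -= XtWy[j] * beta[j]
    if reml:
        return 0.5 * ((n - p) * _LOG2PI + logdet + logdetI + quad)
    return 0.5 * (n * _LOG2PI + logdet + quad)


@dataclass(frozen=True)
class MetaSpec:
    """Specification of one meta-analytic model.

    ``moderators`` are column names: numeric columns enter as-is, non-numeric
    columns are expanded into treatment contrasts with the alphabetically first
    level as reference. ``random`` is ``("study",)`` or ``("study",
    "observation")``; the observation-level component adds a free variance on
    top of the known sampling variances. ``fixed_components`` pins components
    ("study" / "observation") at given values instead of estimating them.
    """

    outcome: str
    variance_column: str
    moderators: tuple[str, ...] = ()
    random: tuple[str, ...] = ("study",)
    estimation: str = "REML"
    study_column: str = "case_study_id"
    fixed_components: dict | None = None

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")
        if "study" not in self.random:
            raise ValueError("the random spec must include the study level")
        for lvl in self.random:
            if lvl not in ("study", "observation"):
                raise ValueError(f"unknown random level {lvl!r}")


@dataclass
class MetaFit:
    """A fitted multilevel meta-model."""

    coefficients: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    sigma2: dict  # variance components per random level
    QM: float
    QM_df: int
    QM_p: float
    loglik: float
    loglik_ml: float
    AIC_ML: float
    k_params: int
    converged: bool
    n_obs: int
    n_studies: int
    term_map: dict  # term -> design-matrix column names
    term_levels: dict  # categorical term -> (reference, all levels)
    spec: MetaSpec
    fitted: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)

    @property
    def components_start(self) -> tuple[float, ...]:
        """Estimated components, usable as a warm start for a related fit."""
        return tuple(self.sigma2.get(lvl, 0.0) for lvl in self.spec.random)


# ---------------------------------------------------------------------------
# design matrix


def _build_design(data: pd.DataFrame, moderators: tuple[str, ...]):
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_map: dict[str, list[str]] = {"intercept": ["intercept"]}
    term_levels: dict[str, tuple[str, list[str]]] = {}
    for term in moderators:
        if term not in data.columns:
            raise ValueError(f"moderator {term!r} not found in the data")
        col = data[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            term_map[term] = [term]
        else:
            levels = sorted(col.astype(str).unique())
            ref, rest = levels[0], levels[1:]
            term_levels[term] = (ref, levels)
            term_map[term] = []
            for lv in rest:
                cols.append((col.astype(str) == lv).to_numpy(dtype=float))
                name = f"{term}[{lv}]"
                names.append(name)
                term_map[term].append(name)
            if not rest:
                raise ValueError(
                    f"moderator {term!r} has a single level; design is rank deficient"
                )
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via the QR decomposition
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased terms: {bad or names}")
    return X, names, term_map, term_levels


# ---------------------------------------------------------------------------
# profiled likelihood (Sherman-Morrison over study blocks)


class _Likelihood:
    def __init__(self, y, X, v, study_idx, n_studies):
        self.sidx = np.ascontiguousarray(study_idx, dtype=np.int64)
        self.n_s = n_studies
        self.n, self.p = X.shape
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.y = np.ascontiguousarray(y, dtype=np.float64)
        self.v = np.ascontiguousarray(v, dtype=np.float64)
        self._flat_idx = (self.sidx[:, None] * self.p + np.arange(self.p)).ravel()
        # REML likelihoods are reported in the +0.5 log|X'X| convention
        self._reml_const = 0.5 * np.linalg.slogdet(self.X.T @ self.X)[1]

    def nll_fast(self, tau2: float, sig2: float, reml: bool) -> float:
        """Objective value only; JIT kernel when numba is available."""
        if tau2 < 0 or sig2 < 0 or not np.isfinite(tau2) or not np.isfinite(sig2):
            return np.inf
        if _HAVE_NUMBA:
            return _nll_kernel(
                self.y, self.X, self.v, self.sidx, self.n_s, tau2, sig2, reml
            )
        return self.nll(tau2, sig2, reml)[0]

    def parts(self, tau2: float, sig2: float):
        d = self.v + sig2
        a = 1.0 / d
        S1 = np.bincount(self.sidx, a, minlength=self.n_s)
        g = tau2 / (1.0 + tau2 * S1)
        Aw = self.X * a[:, None]
        # per-study column sums in a single flattened bincount
        Sx = np.bincount(
            self._flat_idx, Aw.ravel(), minlength=self.n_s * self.p
        ).reshape(self.n_s, self.p)
        Sy = np.bincount(self.sidx, self.y * a, minlength=self.n_s)
        gSx = Sx * g[:, None]
        XtViX = self.X.T @ Aw - gSx.T @ Sx
        XtViy = Aw.T @ self.y - gSx.T @ Sy
        yViy = float(self.y @ (self.y * a) - g @ (Sy**2))
        logdetV = float(np.log(d).sum() + np.log1p(tau2 * S1).sum())
        return XtViX, XtViy, yViy, logdetV

    def nll(self, tau2: float, sig2: float, reml: bool):
        if tau2 < 0 or sig2 < 0 or not np.isfinite(tau2) or not np.isfinite(sig2):
            return np.inf, None, None
        XtViX, XtViy, yViy, logdetV = self.parts(tau2, sig2)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None, None
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        quad = yViy - float(XtViy @ beta)
        if reml:
            val = (
                0.5 * ((self.n - self.p) * _LOG2PI + logdetV + logdetXtViX + quad)
                - self._reml_const
            )
        else:
            val = 0.5 * (self.n * _LOG2PI + logdetV + quad)
        return val, beta, XtViX


def _nelder_mead(obj, x0, step=0.1, fatol=1e-9, xatol=1e-5, maxiter=500):
    """Minimal Nelder-Mead (reflection/expansion/contraction/shrink).

    Tuned for the 1-2 dimensional variance-component searches here, where the
    per-call overhead of a general-purpose optimizer would dominate the
    JIT-compiled objective.
    """
    n = len(x0)
    sim = np.empty((n + 1, n))
    sim[0] = x0
    for i in range(n):
        sim[i + 1] = x0
        sim[i + 1, i] += step if x0[i] == 0 else max(0.4 * abs(x0[i]), 0.02)
    f = np.array([obj(x) for x in sim])
    it = 0
    while it < maxiter:
        order = np.argsort(f)
        sim, f = sim[order], f[order]
        if (f[-1] - f[0] < fatol and np.abs(sim[1:] - sim[0]).max() < xatol) or not np.isfinite(
            f[0]
        ):
            break
        centroid = sim[:-1].mean(axis=0)
        xr = centroid + (centroid - sim[-1])
        fr = obj(xr)
        if fr < f[0]:
            xe = centroid + 2.0 * (centroid - sim[-1])
            fe = obj(xe)
            sim[-1], f[-1] = (xe, fe) if fe < fr else (xr, fr)
        elif fr < f[-2]:
            sim[-1], f[-1] = xr, fr
        else:
            xc = centroid + 0.5 * (sim[-1] - centroid)
            fc = obj(xc)
            if fc < f[-1]:
                sim[-1], f[-1] = xc, fc
            else:  # shrink
                for i in range(1, n + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    f[i] = obj(sim[i])
        it += 1
    best = int(np.argmin(f))
    return sim[best], float(f[best]), it < maxiter


def _optimize_components(lik, free, fixed_vals, reml, start):
    """Minimize the profiled negative log-likelihood over the free components.

    Components are optimized on the square-root scale (a smooth
    reparametrization of the [0, inf) constraint) with Nelder-Mead; restarts
    from small and moderate heterogeneity are tried when the warm start does
    not converge.
    """

    def comp_of(s):
        vals = dict(fixed_vals)
        for name, si in zip(free, s):
            vals[name] = si * si
        return vals.get("study", 0.0), vals.get("observation", 0.0)

    def obj(s):
        tau2, sig2 = comp_of(s)
        return lik.nll_fast(tau2, sig2, reml)

    if not free:
        tau2, sig2 = comp_of(())
        return (tau2, sig2), True
    s0 = np.sqrt(np.asarray(start, dtype=float))
    best_x, best_f, best_ok = None, np.inf, False
    for trial in (s0, np.full(len(free), 0.05), np.full(len(free), 0.45)):
        x, fval, ok = _nelder_mead(obj, trial)
        if fval < best_f - 1e-12:
            best_x, best_f, best_ok = x, fval, ok
        if np.isfinite(best_f) and trial is s0 and best_ok:
            break  # warm start converged; skip the restarts
    if not np.isfinite(best_f):
        raise RuntimeError(
            "variance-component optimization failed to find a finite likelihood"
        )
    return comp_of(best_x), best_ok


# ---------------------------------------------------------------------------
# public fitting interface


def fit_meta(data: pd.DataFrame, spec: MetaSpec, start=None) -> MetaFit:
    """Fit the multilevel weighted meta-analytic model described by ``spec``.

    ``start`` optionally warm-starts the variance-component search (a tuple in
    the order of ``spec.random``), which substantially speeds up repeated fits
    on resampled versions of the same data.
    """
    for col in (spec.outcome, spec.variance_column, spec.study_column):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found in the data")
    y = data[spec.outcome].to_numpy(dtype=float)
    v = data[spec.variance_column].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("all known sampling variances must be strictly positive")
    X, names, term_map, term_levels = _build_design(data, spec.moderators)
    n, p = X.shape
    sidx, studies = pd.factorize(data[spec.study_column], sort=True)
    lik = _Likelihood(y, X, v, sidx, len(studies))

    fixed = dict(spec.fixed_components or {})
    free = [lvl for lvl in ("study", "observation") if lvl in spec.random and lvl not in fixed]
    if n < p + 1 + len(free):
        raise ValueError(
            f"need at least {p + 1 + len(free)} observations for {p} fixed "
            f"parameters and {len(free)} variance components"
        )
    for lvl, val in fixed.items():
        if val < 0:
            raise ValueError("fixed variance components must be >= 0")
    if start is None:
        start = [0.02] * len(free)
    else:
        start = [max(float(s), 1e-6) for s in list(start)[: len(free)]]
        start += [0.02] * (len(free) - len(start))

    reml = spec.estimation == "REML"
    (tau2, sig2), converged = _optimize_components(lik, free, fixed, reml, start)
    nll, beta, XtViX = lik.nll(tau2, sig2, reml)
    if beta is None:
        raise RuntimeError("likelihood is degenerate at the optimum")
    vcov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(vcov))

    # ML log-likelihood / AIC (refit components under ML when estimating by REML,
    # since compared models may differ in their fixed effects).
    k_params = p + len(free)
    if reml and free:
        (tau2_ml, sig2_ml), _ = _optimize_components(
            lik, free, fixed, False, [max(tau2, 1e-6), max(sig2, 1e-6)][: len(free)]
        )
        nll_ml = lik.nll(tau2_ml, sig2_ml, False)[0]
    else:
        nll_ml = lik.nll(tau2, sig2, False)[0]
    loglik_ml = -nll_ml
    aic_ml = 2.0 * nll_ml + 2.0 * k_params

    coef = pd.Series(beta, index=names)
    mod_cols = [c for c in names if c != "intercept"]
    if mod_cols:
        idx = [names.index(c) for c in mod_cols]
        b = beta[idx]
        try:
            qm = float(b @ np.linalg.solve(vcov[np.ix_(idx, idx)], b))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular moderator sub-covariance: {exc}") from exc
        qm_df = len(idx)
        qm_p = float(stats.chi2.sf(qm, qm_df))
    else:
        qm, qm_df, qm_p = 0.0, 0, 1.0

    sigma2 = {}
    if "study" in spec.random:
        sigma2["study"] = float(tau2)
    if "observation" in spec.random:
        sigma2["observation"] = float(sig2)

    fitted = X @ beta
    return MetaFit(
        coefficients=coef,
        se=pd.Series(se, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        sigma2=sigma2,
        QM=qm,
        QM_df=qm_df,
        QM_p=qm_p,
        loglik=float(-nll),
        loglik_ml=float(loglik_ml),
        AIC_ML=float(aic_ml),
        k_params=k_params,
        converged=converged,
        n_obs=n,
        n_studies=len(studies),
        term_map={k: list(vs) for k, vs in term_map.items()},
        term_levels=term_levels,
        spec=spec,
        fitted=fitted,
        resid=y - fitted,
    )


def wald_qm(fit: MetaFit, terms) -> tuple[float, int, float]:
    """Wald-type chi-square test that all coefficients of ``terms`` are zero."""
    if isinstance(terms, str):
        terms = [terms]
    cols: list[str] = []
    for term in terms:
        if term not in fit.term_map:
            raise ValueError(f"term {term!r} not in the fitted model")
        cols.extend(fit.term_map[term])
    b = fit.coefficients[cols].to_numpy()
    V = fit.vcov.loc[cols, cols].to_numpy()
    try:
        qm = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular sub-covariance for terms {terms}: {exc}") from exc
    df = len(cols)
    return qm, df, float(stats.chi2.sf(qm, df))


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def grand_means(fit: MetaFit, term: str = "driver") -> pd.DataFrame:
    """Per-group mean effects with Wald 95% CIs, on the Fisher-z scale.

    Obtained by linear combination of the fitted coefficients (intercept plus
    the group's treatment contrast); other moderators, if any, are held at
    their reference level / zero. p-values test each group mean against zero.
    """
    if term not in fit.term_levels:
        raise ValueError(f"term {term!r} is not a categorical moderator of the fit")
    ref, levels = fit.term_levels[term]
    names = list(fit.coefficients.index)
    rows = []
    for lv in levels:
        L = np.zeros(len(names))
        L[names.index("intercept")] = 1.0
        if lv != ref:
            L[names.index(f"{term}[{lv}]")] = 1.0
        est = float(L @ fit.coefficients.to_numpy())
        se = float(np.sqrt(L @ fit.vcov.to_numpy() @ L))
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
        rows.append(
            {
                "group": lv,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
                "p": p,
                "signif": _stars(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# publication-bias diagnostics


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p: float
    df: int
    k: int


def _zv_from(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return data["z"].to_numpy(dtype=float), data["var_z"].to_numpy(dtype=float)
    return (
        np.array([e.z for e in data], dtype=float),
        np.array([e.var_z for e in data], dtype=float),
    )


def egger_test(data) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    Regresses the standardized effect z_i/SE_i on precision 1/SE_i; the
    intercept is tested against zero with a t-test on k-2 degrees of freedom.
    A significantly positive intercept indicates small-study (publication)
    bias toward positive effects.
    """
    z, v = _zv_from(data)
    k = z.size
    if k < 3:
        raise ValueError(f"Egger's regression needs at least 3 effects, got {k}")
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        raise ValueError("Egger's regression is undefined with constant SEs")
    res = stats.linregress(1.0 / se, z / se)
    tval = res.intercept / res.intercept_stderr
    df = k - 2
    p = 2.0 * stats.t.sf(abs(tval), df)
    return EggerResult(
        intercept=float(res.intercept),
        se=float(res.intercept_stderr),
        t=float(tval),
        p=float(p),
        df=df,
        k=k,
    )


def funnel_data(data) -> pd.DataFrame:
    """Plot-ready funnel table: effect, its SE, and the driver group."""
    if isinstance(data, pd.DataFrame):
        if data.empty:
            raise ValueError("funnel_data needs at least one effect")
        out = data[["z", "var_z"]].copy()
        out["se"] = np.sqrt(out.pop("var_z"))
        out["group"] = data["driver"].to_numpy() if "driver" in data else "all"
        return out.reset_index(drop=True)
    if not data:
        raise ValueError("funnel_data needs at least one effect")
    return pd.DataFrame(
        {
            "z": [e.z for e in data],
            "se": [math.sqrt(e.var_z) for e in data],
            "group": [e.driver for e in data],
        }
    )
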