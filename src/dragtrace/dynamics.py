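"""Longitudinal models of clonal diversity: gamma GLMM with a breakpoint.

Observations are positive diversity values y_itr (mouse i, time t, replicate
r) modeled as Gamma(shape nu, mean mu_it) with

    log mu_it = beta0 + u_i + beta1 * t + beta2 * max(0, t - t_b),

where u_i ~ N(0, sigma_u^2) is a per-mouse random intercept.  The marginal
likelihood integrates u_i by adaptive Gauss-Hermite quadrature; the
breakpoint t_b is estimated by profiling the marginal likelihood over a
grid.  Null models (intercept-only and log-linear) share the same random
effect structure, so model comparison by AIC is apples-to-apples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import gammaln, logsumexp

MODEL_KINDS = ("intercept", "linear", "breakpoint")


def _design(kind: str, t: np.ndarray, breakpoint: float | None) -> np.ndarray:
    if kind == "intercept":
        return np.ones((t.size, 1))
    if kind == "linear":
        return np.column_stack([np.ones_like(t), t])
    if kind == "breakpoint":
        if breakpoint is None:
            raise ValueError("breakpoint design needs a breakpoint time")
        return np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - breakpoint)])
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class _Data:
    mouse_idx: np.ndarray
    t: np.ndarray
    y: np.ndarray
    mice: list
    signature: tuple

    @classmethod
    def from_frame(cls, observations: pd.DataFrame) -> "_Data":
        req = {"mouse", "t", "y"}
        if not req <= set(observations.columns):
            raise ValueError(f"observations must have columns {sorted(req)}")
        y = observations["y"].to_numpy(dtype=float)
        if (y <= 0).any():
            raise ValueError("gamma family requires strictly positive responses")
        t = observations["t"].to_numpy(dtype=float)
        mice = sorted(observations["mouse"].unique().tolist())
        idx = observations["mouse"].map({m: i for i, m in enumerate(mice)}).to_numpy()
        sig = (len(y), float(y.sum()), float(t.sum()), len(mice))
        return cls(mouse_idx=idx, t=t, y=y, mice=mice, signature=sig)


class _MarginalLoglik:
    """Marginal log-likelihood of the gamma GLMM, adaptive Gauss-Hermite."""

    def __init__(self, data: _Data, X: np.ndarray, n_quad: int = 9):
        self.data = data
        self.X = X
        self.n_mice = len(data.mice)
        nodes, weights = hermegauss(n_quad)  # for N(0,1)-weighted integrals
        self.nodes = nodes
        self.logw = np.log(weights) - 0.5 * np.log(2.0 * np.pi)
        # per-mouse observation counts
        self.n_i = np.bincount(data.mouse_idx, minlength=self.n_mice).astype(float)

    def __call__(self, params: np.ndarray) -> float:
        k = self.X.shape[1]
        beta = params[:k]
        # broad box on the variance parameters keeps the degenerate
        # zero-residual case (shape -> inf) from overflowing
        sigma = np.exp(np.clip(params[k], -10.0, 5.0))
        shape = np.exp(np.clip(params[k + 1], -10.0, 20.0))
        d = self.data
        eta = self.X @ beta
        # sufficient per-mouse pieces: g_i(u) = A_i - shape*n_i*u - shape*C_i*e^(-u) - u^2/(2 s^2)
        c = d.y * np.exp(-eta)
        C = np.bincount(d.mouse_idx, weights=c, minlength=self.n_mice)
        A = np.bincount(
            d.mouse_idx,
            weights=shape * (np.log(shape) - eta) + (shape - 1.0) * np.log(d.y),
            minlength=self.n_mice,
        ) - self.n_i * gammaln(shape)
        nsh = shape * self.n_i
        # mode of g_i by Newton (g is strictly concave in u)
        u = np.zeros(self.n_mice)
        inv_s2 = 1.0 / sigma**2
        for _ in range(50):
            e = np.exp(-u)
            grad = -nsh + shape * C * e - u * inv_s2
            hess = -shape * C * e - inv_s2
            step = grad / hess
            step = np.clip(step, -2.0, 2.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-12:
                break
        e = np.exp(-u)
        hess = -shape * C * e - inv_s2
        s_hat = 1.0 / np.sqrt(-hess)
        # adaptive nodes u_ik = u_i + s_hat_i * x_k, standard AGQ weights
        U = u[:, None] + s_hat[:, None] * self.nodes[None, :]
        with np.errstate(over="ignore"):
            G = (
                A[:, None]
                - nsh[:, None] * U
                - shape * C[:, None] * np.exp(-U)
                - 0.5 * U**2 * inv_s2
                - np.log(sigma)
            )
        log_int = logsumexp(
            G + self.logw[None, :] + 0.5 * self.nodes[None, :] ** 2 + np.log(s_hat)[:, None],
            axis=1,
        )
        val = float(np.sum(log_int))
        return val if np.isfinite(val) else -1e12


@dataclass
class BreakpointFit:
    """A fitted gamma mixed model (possibly with a profiled breakpoint)."""

    kind: str
    beta: np.ndarray  # fixed effects on the log scale
    breakpoint: float | None
    sigma_u: float
    shape: float
    loglik: float
    k_params: int
    aic: float
    n_obs: int
    t_range: tuple[float, float]
    data_signature: tuple
    profile: pd.DataFrame | None = None  # t_b grid vs profile loglik
    cov_beta: np.ndarray | None = None
    converged: bool = True

    @property
    def slope_before(self) -> float | None:
        return float(self.beta[1]) if self.beta.size > 1 else None

    @property
    def slope_change(self) -> float | None:
        return float(self.beta[2]) if self.beta.size > 2 else None

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "beta": self.beta.tolist(),
            "breakpoint": self.breakpoint,
            "sigma_u": self.sigma_u,
            "shape": self.shape,
            "loglik": self.loglik,
            "k_params": self.k_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "mean_convention": "conditional mean at u_i = 0 (median mouse)",
        }


def _init_params(data: _Data, X: np.ndarray) -> np.ndarray:
    logy = np.log(data.y)
    beta, *_ = np.linalg.lstsq(X, logy, rcond=None)
    resid = logy - X @ beta
    var = max(float(np.var(resid)), 1e-3)
    return np.concatenate([beta, [np.log(0.5 * np.sqrt(var) + 1e-3)], [np.log(1.0 / var)]])


def _optimize(fun: _MarginalLoglik, x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    neg = lambda p: -fun(p)
    res = optimize.minimize(neg, x0, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    res2 = optimize.minimize(neg, res.x, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
    best = res2 if res2.fun <= res.fun else res
    return best.x, -best.fun, bool(best.success or res.success)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps**2)
    return H


def _finalize(
    data: _Data,
    kind: str,
    breakpoint: float | None,
    params: np.ndarray,
    loglik: float,
    k_extra: int,
    n_quad: int,
    profile: pd.DataFrame | None,
    converged: bool,
) -> BreakpointFit:
    X = _design(kind, data.t, breakpoint)
    kf = X.shape[1]
    fun = _MarginalLoglik(data, X, n_quad=n_quad)
    H = _numerical_hessian(fun, params)
    cov = None
    try:
        cov_full = np.linalg.inv(-H)
        if np.all(np.diag(cov_full) > 0):
            cov = cov_full[:kf, :kf]
    except np.linalg.LinAlgError:
        pass
    k = kf + 2 + k_extra  # fixed effects + sigma_u + shape (+ profiled breakpoint)
    return BreakpointFit(
        kind=kind,
        beta=params[:kf].copy(),
        breakpoint=breakpoint,
        sigma_u=float(np.exp(np.clip(params[kf], -10.0, 5.0))),
        shape=float(np.exp(np.clip(params[kf + 1], -10.0, 20.0))),
        loglik=loglik,
        k_params=k,
        aic=2.0 * k - 2.0 * loglik,
        n_obs=data.y.size,
        t_range=(float(data.t.min()), float(data.t.max())),
        data_signature=data.signature,
        profile=profile,
        cov_beta=cov,
        converged=converged,
    )


def fit_breakpoint_glmm(
    observations: pd.DataFrame,
    breakpoint_grid=None,
    n_quad: int = 9,
) -> BreakpointFit:
    """Fit the breakpoint gamma GLMM, profiling t_b over a grid.

    ``observations``: long-format frame with columns mouse, t, replicate
    (optional), y.  The default grid is 5..10 months in 0.5-month steps,
    clipped to the interior of the observed time range.
    """
    data = _Data.from_frame(observations)
    if len(data.mice) < 2:
        raise ValueError("need >= 2 mice")
    if np.unique(data.t).size < 3:
        raise ValueError("need >= 3 distinct timepoints")
    if breakpoint_grid is None:
        breakpoint_grid = np.arange(5.0, 10.0 + 1e-9, 0.5)
    grid = np.asarray(list(breakpoint_grid), dtype=float)
    lo, hi = data.t.min(), data.t.max()
    grid = grid[(grid > lo) & (grid < hi)]
    if grid.size == 0:
        raise ValueError("breakpoint grid has no point inside the observed time range")
    best = None
    warm = None
    prof_rows = []
    for tb in grid:
        X = _design("breakpoint", data.t, tb)
        fun = _MarginalLoglik(data, X, n_quad=n_quad)
        x0 = _init_params(data, X) if warm is None else warm
        params, ll, ok = _optimize(fun, x0)
        warm = params
        prof_rows.append({"breakpoint": tb, "loglik": ll})
        if best is None or ll > best[1]:
            best = (tb, ll, params, ok)
    tb, ll, params, ok = best
    profile = pd.DataFrame(prof_rows)
    return _finalize(data, "breakpoint", float(tb), params, ll, k_extra=1, n_quad=n_quad, profile=profile, converged=ok)


def _fit_kind(observations: pd.DataFrame, kind: str, n_quad: int = 9) -> BreakpointFit:
    data = _Data.from_frame(observations)
    X = _design(kind, data.t, None)
    fun = _MarginalLoglik(data, X, n_quad=n_quad)
    params, ll, ok = _optimize(fun, _init_params(data, X))
    return _finalize(data, kind, None, params, ll, k_extra=0, n_quad=n_quad, profile=None, converged=ok)


def fit_null_models(observations: pd.DataFrame, n_quad: int = 9) -> dict[str, BreakpointFit]:
    """Intercept-only and log-linear gamma GLMMs with the same random effect."""
    return {
        "intercept": _fit_kind(observations, "intercept", n_quad),
        "linear": _fit_kind(observations, "linear", n_quad),
    }


def compare_models(fits: list[BreakpointFit]) -> pd.DataFrame:
    """AIC selection table; ties broken by fewer parameters."""
    sigs = {f.data_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("fits were not computed on identical data")
    rows = [
        {"kind": f.kind, "k": f.k_params, "loglik": f.loglik, "aic": f.aic} for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table


def predict_mean(fit: BreakpointFit, times, level: float = 0.95) -> pd.DataFrame:
    """Population mean trajectory (conditional on u_i = 0) with a delta-method
    confidence band on the log scale.  Times outside +/-20% of the training
    range trigger an extrapolation warning."""
    times = np.asarray(list(times), dtype=float)
    lo, hi = fit.t_range
    span = hi - lo
    if ((times < lo - 0.2 * span) | (times > hi + 0.2 * span)).any():
        warnings.warn("prediction times extrapolate beyond 20% of the training range", stacklevel=2)
    X = _design(fit.kind, times, fit.breakpoint)
    eta = X @ fit.beta
    if fit.cov_beta is not None:
        se = np.sqrt(np.maximum(0.0, np.einsum("ij,jk,ik->i", X, fit.cov_beta, X)))
    else:
        se = np.full_like(eta, np.nan)
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "t": times,
            "mean": np.exp(eta),
            "lo": np.exp(eta - z * se),
            "hi": np.exp(eta + z * se),
            "se_log": se,
        }
    )


def plot_trajectory(fit: BreakpointFit, observations: pd.DataFrame | None = None, ax=None, n_points: int = 100):
    """Fitted mean diversity trajectory with its 95% confidence ribbon.

    Optionally overlays the raw per-replicate observations (columns mouse,
    t, y).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    lo, hi = fit.t_range
    pred = predict_mean(fit, np.linspace(lo, hi, n_points))
    ax.fill_between(pred["t"], pred["lo"], pred["hi"], color="0.8", label="95% CI")
    ax.plot(pred["t"], pred["mean"], color="black", label="fitted mean")
    if observations is not None:
        for mouse, sub in observations.groupby("mouse"):
            ax.plot(sub["t"], sub["y"], "o", ms=3, alpha=0.6, label=str(mouse))
    if fit.breakpoint is not None:
        ax.axvline(fit.breakpoint, ls=":", color="gray", lw=1)
    ax.set_xlabel("months post-induction")
    ax.set_ylabel("diversity")
    ax.legend(fontsize=7, frameon=False)
    return ax
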