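"""Non-rigid and conventional population response field (pRF) models.

The non-rigid pRF keeps a unit Gaussian response field fixed (center 0,
sigma 1) and fits, per cortical vertex, the distance ``dx_i >= 0`` of each of
the 18 body parts to the field center.  A body part at ``dx_i = 0`` sits at
the center of the vertex's response field; at ``dx_i = dx_max = 10`` the
Gaussian is effectively zero and the part is absent from the field.  The
predicted BOLD timeseries is the stimulus design weighted by the field,
convolved with the canonical HRF, and scaled by a single amplitude beta:

    g_i   = exp(-dx_i^2 / 2)
    r(t)  = sum_i s(x_i, t) g_i
    p(t)  = (r * h)(t)          (convolution restarted at run boundaries)
    y(t)  = beta p(t) + noise

The conventional model instead slides a Gaussian (center x0, width sigma)
along the rigid homunculus axis x_i = 1..18.  Both models are fitted by
multi-start box-constrained trust-region least squares.

Derived per-vertex metrics: the pRF center (body part with minimal distance,
ties resolved by the floored mean index), and the pRF size (normalized-
proximity-weighted count of body parts within the half-width-at-half-maximum
of the unit Gaussian, scaled by FWHM/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .task_design import DesignMatrix, HRFKernel

__all__ = [
    "FWHM",
    "HALF_WIDTH",
    "FitOptions",
    "NonRigidPRF",
    "ConventionalPRF",
    "nonrigid_field",
    "conventional_field",
    "condition_regressors",
    "predict_timeseries",
    "fit_nonrigid",
    "fit_conventional",
    "fit_vertices",
    "prf_center",
    "prf_size",
    "goodness_of_fit",
    "select_vertices",
]

#: Full width at half maximum of the unit-sigma Gaussian response field.
FWHM: float = 2.0 * np.sqrt(2.0 * np.log(2.0))
#: Half window used by the pRF-size metric (body parts are fitted on one
#: side of the symmetric field only).
HALF_WIDTH: float = FWHM / 2.0


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the pRF fitting procedure.

    dx_max
        Upper bound on fitted body-part distances (default 10, where the
        unit Gaussian is numerically zero).
    tie_tol
        Absolute tolerance under which minimal distances count as tied for
        the center rule.
    n_params
        Parameter count used by the goodness-of-fit F statistic: the 18
        distances plus the amplitude (19 for the full protocol, giving the
        (19, 837) degrees of freedom at T = 856).
    sigma_bounds, sigma_starts
        Width bounds and multi-start widths of the conventional model.
    """

    dx_max: float = 10.0
    tie_tol: float = 1e-6
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 200
    sigma_bounds: tuple[float, float] = (0.1, 20.0)
    sigma_starts: tuple[float, ...] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.dx_max <= 0:
            raise ValueError("dx_max must be positive")
        if self.tie_tol <= 0:
            raise ValueError("tie_tol must be positive")


@dataclass(frozen=True)
class NonRigidPRF:
    """One vertex's fitted non-rigid response field."""

    dx: np.ndarray
    beta: float
    center: int
    size: float
    r2: float
    f_stat: float
    p_value: float
    sse: float
    converged: bool = True
    degenerate: bool = False

    @property
    def negative_beta(self) -> bool:
        return self.beta < 0


@dataclass(frozen=True)
class ConventionalPRF:
    """One vertex's fitted rigid-axis Gaussian pRF."""

    x0: float
    sigma: float
    beta: float
    r2: float
    f_stat: float
    p_value: float
    sse: float
    converged: bool = True
    degenerate: bool = False


def nonrigid_field(dx: np.ndarray, dx_max: float = 10.0) -> np.ndarray:
    """Response weight of each body part: ``g_i = exp(-dx_i**2 / 2)``.

    The response field is a unit Gaussian with center 0 and sigma 1; only
    non-negative distances up to ``dx_max`` are admitted.
    """
    dx = np.asarray(dx, dtype=float)
    if np.any(dx < 0) or np.any(dx > dx_max):
        raise ValueError(f"distances must lie in [0, {dx_max}]")
    return np.exp(-0.5 * dx**2)


def conventional_field(
    x0: float, sigma: float, n_conditions: int = 18
) -> np.ndarray:
    """Gaussian tuning over the rigid body-part axis 1..n."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xi = np.arange(1, n_conditions + 1, dtype=float)
    return np.exp(-((x0 - xi) ** 2) / (2.0 * sigma**2))


def condition_regressors(design: DesignMatrix, hrf: HRFKernel) -> np.ndarray:
    """HRF-convolved regressor per condition, shape (T, n_conditions).

    Convolution is performed within each scanner run separately (the
    hemodynamic response does not carry across run boundaries) and the runs
    are concatenated in protocol order.  The model prediction for any
    response field g is then the single matrix product ``C @ g``.
    """
    if abs(design.tr - hrf.tr) > 1e-9:
        raise ValueError(
            f"design (tr={design.tr}) and HRF (tr={hrf.tr}) sampling differ"
        )
    n_cond, T = design.s.shape
    C = np.empty((T, n_cond))
    for sl in design.run_slices():
        seg = design.s[:, sl].astype(float)
        n = sl.stop - sl.start
        for i in range(n_cond):
            C[sl, i] = np.convolve(seg[i], hrf.values)[:n]
    return C


def predict_timeseries(
    weights: np.ndarray, design: DesignMatrix, hrf: HRFKernel
) -> np.ndarray:
    """Forward-model prediction p(t) for a given response field."""
    return condition_regressors(design, hrf) @ np.asarray(weights, dtype=float)


def goodness_of_fit(
    y: np.ndarray, prediction: np.ndarray, n_params: int
) -> tuple[float, float, float]:
    """F statistic, p-value and R^2 of a prediction against the zero null.

    The data are mean-free percent-signal-change timeseries, so the null
    model is the all-zero signal and no intercept is counted: the hypothesis
    degrees of freedom equal ``n_params`` and the error degrees of freedom
    ``T - n_params`` (19 and 837 for the full 856-volume protocol).
    """
    y = np.asarray(y, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    T = y.size
    if n_params >= T:
        raise ValueError("n_params must be smaller than the number of volumes")
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        return 0.0, 1.0, 0.0
    resid = y - prediction
    sse = float(resid @ resid)
    r2 = max(0.0, 1.0 - sse / ss_tot)
    df_h = n_params
    df_e = T - n_params
    if sse == 0.0:
        return np.inf, 0.0, 1.0
    f_stat = ((ss_tot - sse) / df_h) / (sse / df_e)
    f_stat = max(f_stat, 0.0)
    p = float(f_dist.sf(f_stat, df_h, df_e))
    return float(f_stat), p, float(r2)


def prf_center(dx: np.ndarray, tie_tol: float = 1e-6) -> int:
    """Preferred body part: 1-based index of the minimal distance.

    When several distances tie for the minimum (within ``tie_tol``), the
    center is the floor of the mean tied index.
    """
    dx = np.asarray(dx, dtype=float)
    tied = np.flatnonzero(dx <= dx.min() + tie_tol) + 1
    if tied.size == 1:
        return int(tied[0])
    return int(np.floor(tied.mean()))


def normalized_proximity(
    dx: np.ndarray, dx_max: float = 10.0, truncated: bool = False
) -> np.ndarray:
    """Linear proximity ``(dx_max - dx) / dx_max`` (1 = field center).

    In truncated mode the proximity is zeroed beyond the half-width-at-half-
    maximum window, the form entering the pRF-size metric; the untruncated
    form is used when averaging full response fields.
    """
    dx = np.asarray(dx, dtype=float)
    p = (dx_max - dx) / dx_max
    if truncated:
        p = np.where(dx <= HALF_WIDTH, p, 0.0)
    return p


def prf_size(dx: np.ndarray, dx_max: float = 10.0) -> float:
    """pRF size: proximity-weighted body-part count within the HWHM window.

    ``size = sum_i P(dx_i) * FWHM/2`` with ``P`` the truncated normalized
    proximity, so a field containing exactly one body part at its center has
    size ~1.18 (one body part's worth of field).
    """
    p = normalized_proximity(dx, dx_max, truncated=True)
    return float(p.sum() * HALF_WIDTH)


def _degenerate_nonrigid(n_cond: int, opts: FitOptions) -> NonRigidPRF:
    dx = np.full(n_cond, opts.dx_max)
    return NonRigidPRF(
        dx=dx,
        beta=0.0,
        center=prf_center(dx, opts.tie_tol),
        size=prf_size(dx, opts.dx_max),
        r2=0.0,
        f_stat=0.0,
        p_value=1.0,
        sse=0.0,
        converged=True,
        degenerate=True,
    )


def fit_nonrigid(
    y: np.ndarray,
    design: DesignMatrix,
    hrf: HRFKernel,
    opts: FitOptions | None = None,
    *,
    regressors: np.ndarray | None = None,
) -> NonRigidPRF:
    """Fit the non-rigid pRF to one vertex timeseries.

    The problem is non-convex chiefly through the discrete choice of which
    body part anchors the field, so one start per candidate center is used:
    start k places part k at the center (dx=0) and every other part at
    dx_max/2.  Each start is refined by box-constrained trust-region least
    squares over (dx, beta) jointly, with beta initialized at its closed-form
    least-squares value and an analytic Jacobian; the lowest-SSE solution is
    returned.  ``regressors`` may pass a precomputed
    :func:`condition_regressors` matrix when fitting many vertices.
    """
    if opts is None:
        opts = FitOptions()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("timeseries contains non-finite values")
    C = condition_regressors(design, hrf) if regressors is None else regressors
    T, n_cond = C.shape
    if y.size != T:
        raise ValueError(f"timeseries length {y.size} != design volumes {T}")
    if np.ptp(y) == 0.0:
        return _degenerate_nonrigid(n_cond, opts)

    def residual(theta: np.ndarray) -> np.ndarray:
        g = np.exp(-0.5 * theta[:-1] ** 2)
        return y - theta[-1] * (C @ g)

    def jacobian(theta: np.ndarray) -> np.ndarray:
        dx, beta = theta[:-1], theta[-1]
        g = np.exp(-0.5 * dx**2)
        J = np.empty((T, n_cond + 1))
        # d r / d dx_i = -beta * C_i * dg_i/ddx_i = beta * C_i * dx_i * g_i
        J[:, :-1] = C * (beta * dx * g)
        J[:, -1] = -(C @ g)
        return J

    lb = np.concatenate([np.zeros(n_cond), [-np.inf]])
    ub = np.concatenate([np.full(n_cond, opts.dx_max), [np.inf]])

    # score all starts by their closed-form profiled-beta SSE and refine in
    # that order; a start that already explains essentially all variance
    # cannot be beaten meaningfully, so later starts are skipped then
    starts = []
    for k in range(n_cond):
        dx0 = np.full(n_cond, opts.dx_max / 2.0)
        dx0[k] = 0.0
        g0 = np.exp(-0.5 * dx0**2)
        p0 = C @ g0
        denom = float(p0 @ p0)
        beta0 = float(p0 @ y) / denom if denom > 0 else 0.0
        sse0 = float(y @ y) - beta0**2 * denom
        starts.append((sse0, np.concatenate([dx0, [beta0]])))
    starts.sort(key=lambda s: s[0])
    ss_tot = float(y @ y)

    best: optimize.OptimizeResult | None = None
    converged = True
    for _, theta0 in starts:
        try:
            res = optimize.least_squares(
                residual,
                theta0,
                jac=jacobian,
                bounds=(lb, ub),
                method="trf",
                xtol=opts.xtol,
                ftol=opts.ftol,
                gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
        except Exception:  # pragma: no cover - optimizer hard failure
            converged = False
            continue
        if not res.success:
            converged = False
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= 1e-9 * 0.5 * ss_tot:
            break
    if best is None:  # pragma: no cover
        warnings.warn("all optimizer starts failed; returning degenerate fit")
        return _degenerate_nonrigid(n_cond, opts)

    dx = np.clip(best.x[:-1], 0.0, opts.dx_max)
    beta = float(best.x[-1])
    pred = beta * (C @ np.exp(-0.5 * dx**2))
    f_stat, p_value, r2 = goodness_of_fit(y, pred, n_cond + 1)
    resid = y - pred
    return NonRigidPRF(
        dx=dx,
        beta=beta,
        center=prf_center(dx, opts.tie_tol),
        size=prf_size(dx, opts.dx_max),
        r2=r2,
        f_stat=f_stat,
        p_value=p_value,
        sse=float(resid @ resid),
        converged=converged,
    )


def fit_conventional(
    y: np.ndarray,
    design: DesignMatrix,
    hrf: HRFKernel,
    opts: FitOptions | None = None,
    *,
    regressors: np.ndarray | None = None,
) -> ConventionalPRF:
    """Fit the conventional rigid-axis Gaussian pRF to one vertex.

    Multi-start over every integer center x0 in 1..n crossed with
    ``opts.sigma_starts``, each refined by bounded least squares over
    (x0, sigma, beta).
    """
    if opts is None:
        opts = FitOptions()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("timeseries contains non-finite values")
    C = condition_regressors(design, hrf) if regressors is None else regressors
    T, n_cond = C.shape
    if y.size != T:
        raise ValueError(f"timeseries length {y.size} != design volumes {T}")
    if np.ptp(y) == 0.0:
        return ConventionalPRF(
            x0=(1 + n_cond) / 2.0,
            sigma=opts.sigma_bounds[0],
            beta=0.0,
            r2=0.0,
            f_stat=0.0,
            p_value=1.0,
            sse=0.0,
            degenerate=True,
        )
    xi = np.arange(1, n_cond + 1, dtype=float)

    def residual(theta: np.ndarray) -> np.ndarray:
        x0, sigma, beta = theta
        g = np.exp(-((x0 - xi) ** 2) / (2.0 * sigma**2))
        return y - beta * (C @ g)

    def jacobian(theta: np.ndarray) -> np.ndarray:
        x0, sigma, beta = theta
        d = x0 - xi
        g = np.exp(-(d**2) / (2.0 * sigma**2))
        J = np.empty((T, 3))
        J[:, 0] = beta * (C @ (g * d / sigma**2))
        J[:, 1] = -beta * (C @ (g * d**2 / sigma**3))
        J[:, 2] = -(C @ g)
        return J

    lb = np.array([1.0, opts.sigma_bounds[0], -np.inf])
    ub = np.array([float(n_cond), opts.sigma_bounds[1], np.inf])
    best: optimize.OptimizeResult | None = None
    converged = True
    for x0_start in xi:
        for sigma_start in opts.sigma_starts:
            g0 = np.exp(-((x0_start - xi) ** 2) / (2.0 * sigma_start**2))
            p0 = C @ g0
            denom = float(p0 @ p0)
            beta0 = float(p0 @ y) / denom if denom > 0 else 0.0
            theta0 = np.array([x0_start, sigma_start, beta0])
            res = optimize.least_squares(
                residual,
                theta0,
                jac=jacobian,
                bounds=(lb, ub),
                method="trf",
                xtol=opts.xtol,
                ftol=opts.ftol,
                gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
            if not res.success:
                converged = False
            if best is None or res.cost < best.cost:
                best = res
    assert best is not None
    x0, sigma, beta = best.x
    pred = beta * (C @ np.exp(-((x0 - xi) ** 2) / (2.0 * sigma**2)))
    f_stat, p_value, r2 = goodness_of_fit(y, pred, 3)
    resid = y - pred
    return ConventionalPRF(
        x0=float(x0),
        sigma=float(sigma),
        beta=float(beta),
        r2=r2,
        f_stat=f_stat,
        p_value=p_value,
        sse=float(resid @ resid),
        converged=converged,
    )


def select_vertices(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up vertex selection at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def fit_vertices(
    Y: np.ndarray,
    design: DesignMatrix,
    hrf: HRFKernel,
    opts: FitOptions | None = None,
    model: str = "nonrigid",
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit every row of a vertices x volumes matrix; returns a tidy table.

    For the non-rigid model the table carries dx_1..dx_n, beta, center, size,
    r2, f_stat, p_value and the FDR ``selected`` flag; for the conventional
    model x0/sigma replace the distances.
    """
    if opts is None:
        opts = FitOptions()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    C = condition_regressors(design, hrf)
    rows = []
    if model == "nonrigid":
        for v in range(Y.shape[0]):
            fit = fit_nonrigid(Y[v], design, hrf, opts, regressors=C)
            row = {"vertex_id": v}
            row.update({f"dx_{i+1}": fit.dx[i] for i in range(fit.dx.size)})
            row.update(
                beta=fit.beta,
                center=fit.center,
                size=fit.size,
                r2=fit.r2,
                f_stat=fit.f_stat,
                p_value=fit.p_value,
            )
            rows.append(row)
    elif model == "conventional":
        for v in range(Y.shape[0]):
            cfit = fit_conventional(Y[v], design, hrf, opts, regressors=C)
            rows.append(
                {
                    "vertex_id": v,
                    "x0": cfit.x0,
                    "sigma": cfit.sigma,
                    "beta": cfit.beta,
                    "r2": cfit.r2,
                    "f_stat": cfit.f_stat,
                    "p_value": cfit.p_value,
                }
            )
    else:
        raise ValueError(f"unknown model {model!r}")
    table = pd.DataFrame(rows)
    table["selected"] = select_vertices(table["p_value"].to_numpy(), q)
    return table
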