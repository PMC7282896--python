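"""Gompertz growth-curve fitting for metabolism trajectories.

Daily GPP (and ER) in a newly assembled mesocosm typically rises along a
sigmoid as the biofilm community develops. The three-parameter Gompertz
curve

    Y(t) = K * exp(-lag * exp(-rate * t))

captures that with an upper asymptote ``K`` (the maximum attained rate), a
growth rate ``rate`` (day^-1) and a dimensionless location parameter
``lag`` that shifts the curve along the time axis (large lag = late rise).
This module fits the curve by nonlinear least squares, inverts it
analytically (time to reach a fraction of K), and characterises how the
fitted parameters change along an experimental treatment gradient with a
linear-plus-quadratic contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GompertzFit",
    "gompertz_value",
    "fit_gompertz",
    "time_to_fraction",
    "parameter_trend",
    "TrendResult",
]


@dataclass
class GompertzFit:
    """Fitted Gompertz parameters for one series."""

    K: float
    rate: float
    lag: float
    r2: float
    se_K: float
    se_rate: float
    se_lag: float
    converged: bool
    message: str = ""
    treatment_pct_cattle: float = np.nan
    stream: str = ""

    def value(self, t):
        return gompertz_value(t, self.K, self.lag, self.rate)


def gompertz_value(t, K: float, lag: float, rate: float):
    """Evaluate Y(t) = K * exp(-lag * exp(-rate * t)).

    Strictly increasing in t and bounded in (0, K) for positive parameters;
    Y(0) = K * exp(-lag), Y(inf) = K.
    """
    t = np.asarray(t, dtype=float)
    out = K * np.exp(-lag * np.exp(-rate * t))
    return float(out) if out.ndim == 0 else out


# bounds generous in lag: sparse early data can push the location estimate
# to extreme values, which callers should see flagged rather than clipped
RATE_MAX = 10.0
LAG_MAX = 1e6


def _initial_guess(t: np.ndarray, y: np.ndarray):
    """Heuristic start: K from the series maximum, rate and lag from a
    log-linear regression of log(-log(y/K0)) on t."""
    K0 = float(np.max(y)) * 1.05
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(-np.log(np.clip(y / K0, 1e-12, 1 - 1e-12)))
    ok = np.isfinite(z)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(t[ok], z[ok], 1)
        rate0 = min(max(-slope, 1e-3), RATE_MAX * 0.9)
        lag0 = min(max(np.exp(intercept), 1e-3), LAG_MAX * 0.9)
    else:
        rate0, lag0 = 0.1, 2.0
    return K0, lag0, rate0


def fit_gompertz(
    t,
    y,
    treatment_pct_cattle: float = np.nan,
    stream: str = "",
) -> GompertzFit:
    """Fit the Gompertz curve to a (time, value) series by least squares.

    Needs >= 6 points; series that decrease overall are rejected (the model
    is monotone increasing). Non-convergence and bound-hitting are reported
    on the returned fit via ``converged``/``message``, not raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 6:
        raise ValueError("need >= 6 aligned (t, y) points")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    if np.ptp(y) == 0:
        return GompertzFit(
            K=np.nan, rate=np.nan, lag=np.nan, r2=np.nan,
            se_K=np.nan, se_rate=np.nan, se_lag=np.nan, converged=False,
            message="constant series: sigmoid undefined",
            treatment_pct_cattle=treatment_pct_cattle, stream=stream,
        )
    slope = np.polyfit(t, y, 1)[0]
    if slope < 0:
        return GompertzFit(
            K=np.nan, rate=np.nan, lag=np.nan, r2=np.nan,
            se_K=np.nan, se_rate=np.nan, se_lag=np.nan, converged=False,
            message="overall decreasing series: growth model rejected",
            treatment_pct_cattle=treatment_pct_cattle, stream=stream,
        )
    p0 = _initial_guess(t, y)
    K_max = 10.0 * float(np.max(y))
    bounds = ([1e-12, 1e-12, 1e-12], [K_max, LAG_MAX, RATE_MAX])

    def model(tt, K, lag, rate):
        return gompertz_value(tt, K, lag, rate)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
        )
    except RuntimeError as exc:
        return GompertzFit(
            K=np.nan, rate=np.nan, lag=np.nan, r2=np.nan,
            se_K=np.nan, se_rate=np.nan, se_lag=np.nan, converged=False,
            message=f"optimizer failed: {exc}",
            treatment_pct_cattle=treatment_pct_cattle, stream=stream,
        )
    K, lag, rate = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    message = ""
    if lag > 0.99 * LAG_MAX or rate > 0.99 * RATE_MAX or K > 0.99 * K_max:
        message = "estimate at parameter bound"
    return GompertzFit(
        K=float(K), rate=float(rate), lag=float(lag), r2=r2,
        se_K=float(se[0]), se_rate=float(se[2]), se_lag=float(se[1]),
        converged=True, message=message,
        treatment_pct_cattle=treatment_pct_cattle, stream=stream,
    )


def time_to_fraction(fit: GompertzFit, f: float) -> float:
    """Days until the curve reaches fraction ``f`` of its asymptote K.

    Closed-form inverse t = -(1/rate) * ln(-ln(f) / lag), defined for
    f in (exp(-lag), 1) — the curve starts at K*exp(-lag), so smaller
    fractions are never reached for t >= 0 going forward, and K itself only
    asymptotically.
    """
    lo = np.exp(-fit.lag)
    if not lo < f < 1.0:
        if f == lo:
            return 0.0
        raise ValueError(f"f must be in (exp(-lag), 1) = ({lo:.3g}, 1)")
    return float(-np.log(-np.log(f) / fit.lag) / fit.rate)


@dataclass
class TrendResult:
    """Linear + quadratic contrast of a fitted parameter vs treatment."""

    parameter: str
    slope: float
    slope_se: float
    slope_t: float
    quad: float
    quad_se: float
    quad_t: float
    curvature: bool
    intercept: float
    n: int


def parameter_trend(fits: list[GompertzFit], parameter: str) -> TrendResult:
    """OLS linear and quadratic trend of a Gompertz parameter vs % cattle.

    Fits value ~ 1 + pct + pct^2 over converged fits; curvature is flagged
    when the quadratic coefficient's |t| exceeds 2 (a nonlinear response to
    the dung-replacement gradient). Requires >= 3 distinct treatment levels.
    """
    if parameter not in ("K", "rate", "lag"):
        raise ValueError("parameter must be 'K', 'rate' or 'lag'")
    pts = [
        (f.treatment_pct_cattle, getattr(f, parameter))
        for f in fits
        if f.converged and np.isfinite(f.treatment_pct_cattle)
    ]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct treatment levels")
    X = np.column_stack([np.ones_like(x), x, x**2])
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    dof = max(x.size - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    # pure-linear refit for the reported slope (quadratic term soaks up
    # slope otherwise when curvature is absent but x is uncentred)
    lin = np.column_stack([np.ones_like(x), x])
    lin_coef, *_ = np.linalg.lstsq(lin, y, rcond=None)
    lin_resid = y - lin @ lin_coef
    lin_sigma2 = float(lin_resid @ lin_resid) / max(x.size - 2, 1)
    lin_cov = lin_sigma2 * np.linalg.inv(lin.T @ lin)
    lin_se = np.sqrt(np.diag(lin_cov))
    slope_t = lin_coef[1] / lin_se[1] if lin_se[1] > 0 else np.inf * np.sign(lin_coef[1])
    return TrendResult(
        parameter=parameter,
        slope=float(lin_coef[1]),
        slope_se=float(lin_se[1]),
        slope_t=float(slope_t),
        quad=float(coef[2]),
        quad_se=float(se[2]),
        quad_t=float(tstats[2]),
        curvature=bool(abs(tstats[2]) > 2.0),
        intercept=float(lin_coef[0]),
        n=int(x.size),
    )
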