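"""Quantitative pharmacology: 4PL dose-response fits, absolute IC50,
fold-resistance, Chou-Talalay median-effect / combination-index analysis and
ZIP delta synergy scoring.

Conventions
-----------
* Dose-response plates record *viability* normalized to untreated control
  (control ~ 1, fully inhibited ~ 0); the 4PL curve
  ``y = bottom + (top - bottom) / (1 + (x / ec50)**hill)`` is decreasing in
  dose for hill > 0.
* Combination grids record *inhibition* (fraction affected, fa, in [0, 1]).
* ZIP deltas are reported on the x100 scale so the +-10 interpretation
  thresholds apply directly: mean delta > 10 synergistic, < -10 antagonistic,
  otherwise additive.  Combination index: CI < 1 synergistic, = 1 additive,
  > 1 antagonistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "four_pl",
    "FourPLFit",
    "fit_four_pl",
    "absolute_ic50",
    "fold_resistance",
    "MedianEffectFit",
    "fit_median_effect",
    "combination_index",
    "ZipResult",
    "zip_delta",
    "combination_index_grid",
    "classify_ci",
    "classify_zip",
]


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic; decreasing in dose when ``hill > 0``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    residual_sse: float
    converged: bool


def _fourpl_residuals(theta, logx, y):
    bottom, top, log_ec50, hill = theta
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logx - log_ec50))) - y


def fit_four_pl(doses, responses) -> FourPLFit:
    """Least-squares 4PL fit with 5 deterministic initializations.

    Requires >= 4 distinct positive doses.  Flat (zero-range) data yields
    ``converged = False`` with bottom == top == mean.  The parameterization is
    canonicalized so that ``bottom < top`` (swapping asymptotes and negating
    the slope leaves the curve unchanged).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have matching shapes")
    if np.any(doses <= 0):
        raise ValueError("all doses must be strictly positive")
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses for a 4PL fit")
    if np.any(~np.isfinite(responses)):
        raise ValueError("responses must be finite")

    y_min, y_max = float(responses.min()), float(responses.max())
    if y_max - y_min < 1e-9:
        return FourPLFit(y_min, y_max, float(np.median(doses)), 0.0, 0.0, False)

    logx = np.log(doses)
    mid = 0.5 * (logx.min() + logx.max())
    quarter = 0.25 * (logx.max() - logx.min())
    starts = [
        (y_min, y_max, mid, 1.0),
        (y_min, y_max, mid, 2.0),
        (y_min, y_max, mid - quarter, 1.0),
        (y_min, y_max, mid + quarter, 1.0),
        (y_min, y_max, mid, -1.0),  # increasing data
    ]
    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                _fourpl_residuals, theta0, args=(logx, responses),
                method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:  # pragma: no cover - lm rarely raises
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol)
    if best is None:
        return FourPLFit(y_min, y_max, float(np.median(doses)), 0.0, float("inf"), False)
    sse, sol = best
    bottom, top, log_ec50, hill = sol.x
    if bottom > top:  # canonical orientation
        bottom, top, hill = top, bottom, -hill
    converged = bool(sol.success) and np.isfinite(sol.x).all() and abs(top - bottom) > 1e-9
    return FourPLFit(float(bottom), float(top), float(np.exp(log_ec50)), float(hill),
                     sse, converged)


def absolute_ic50(fit: FourPLFit) -> float | None:
    """Dose at which the fitted curve crosses 0.5 on the control scale.

    Equals ``ec50`` when bottom = 0 and top = 1.  Returns ``None`` ("not
    reached") when the fitted curve never crosses 50% of control, rather than
    an extrapolated number.
    """
    if not fit.converged:
        raise ValueError("cannot derive IC50 from a non-converged fit")
    if not (fit.bottom < 0.5 < fit.top):
        return None
    ratio = (fit.top - 0.5) / (0.5 - fit.bottom)
    return float(fit.ec50 * ratio ** (1.0 / fit.hill))


def fold_resistance(ic50_resistant: float | None, ic50_parental: float | None) -> float | None:
    """IC50 ratio of resistant over parental line; "not reached" propagates."""
    if ic50_resistant is None or ic50_parental is None:
        return None
    if ic50_resistant <= 0 or ic50_parental <= 0:
        raise ValueError("IC50 values must be positive")
    return float(ic50_resistant / ic50_parental)


@dataclass
class MedianEffectFit:
    """Chou median-effect linearization log(fa/(1-fa)) = m * log(d / Dm)."""

    dm: float
    m: float
    r_fit: float
    n_used: int
    n_excluded: int


def fit_median_effect(doses, fa) -> MedianEffectFit:
    """Fit the median-effect line; points with fa at exactly 0 or 1 are
    excluded (logged) since their logit is undefined."""
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    usable = (fa > 0.0) & (fa < 1.0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("median-effect fit: excluded %d points with fa in {0, 1}", n_excluded)
    if usable.sum() < 2:
        raise ValueError("need >= 2 points with fa strictly inside (0, 1)")
    x = np.log(doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct usable doses")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0:
        raise ValueError("degenerate median-effect fit: zero slope")
    dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(dm, m, float(res.rvalue), int(usable.sum()), n_excluded)


def combination_index(d_a: float, d_b: float, fa_observed: float,
                      fit_a: MedianEffectFit, fit_b: MedianEffectFit) -> float:
    """Chou-Talalay CI = d_a / Dx_a + d_b / Dx_b at the observed effect level,
    where ``Dx_i = Dm_i * (fa / (1 - fa))**(1 / m_i)`` is the single-agent dose
    of drug i producing the observed fraction affected."""
    if not (0.0 < fa_observed < 1.0):
        raise ValueError("fa must be strictly inside (0, 1) for the CI")
    ratio = fa_observed / (1.0 - fa_observed)
    dx_a = fit_a.dm * ratio ** (1.0 / fit_a.m)
    dx_b = fit_b.dm * ratio ** (1.0 / fit_b.m)
    return float(d_a / dx_a + d_b / dx_b)


def classify_ci(ci: float, tol: float = 1e-9) -> str:
    if ci < 1.0 - tol:
        return "synergistic"
    if ci > 1.0 + tol:
        return "antagonistic"
    return "additive"


def classify_zip(mean_delta: float) -> str:
    if mean_delta > 10.0:
        return "synergistic"
    if mean_delta < -10.0:
        return "antagonistic"
    return "additive"


# --------------------------------------------------------------------------
# ZIP delta scoring
# --------------------------------------------------------------------------

def _logistic_inhibition(x, log_e, h, floor=0.0):
    """Inhibition rising from ``floor`` at dose 0 to 1, logistic in log-dose."""
    x = np.asarray(x, dtype=float)
    u = np.zeros_like(x)
    pos = x > 0
    u[pos] = np.exp(h * (np.log(x[pos]) - log_e))
    return (floor + u) / (1.0 + u)


def _fit_logistic(doses, y, floor=0.0):
    """Fit (ec50, hill) of the fixed-asymptote logistic; returns params or None."""
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = doses > 0
    if pos.sum() < 2:
        return None

    def resid(theta):
        return _logistic_inhibition(doses, theta[0], theta[1], floor) - y

    mid = float(np.median(np.log(doses[pos])))
    best = None
    for theta0 in [(mid, 1.0), (mid, 2.0), (mid, 0.5)]:
        try:
            sol = optimize.least_squares(resid, theta0, method="lm",
                                         xtol=1e-13, ftol=1e-13, max_nfev=2000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol)
    if best is None or not best[1].success or not np.isfinite(best[1].x).all():
        return None
    log_e, h = best[1].x
    return float(log_e), float(h)


@dataclass
class ZipResult:
    """Per-cell ZIP deltas (x100 scale, NaN on margins/excluded cells), their
    grid mean, and the interpretation class."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    delta: np.ndarray
    mean_delta: float
    interaction_class: str
    n_cells: int
    n_excluded: int


def zip_delta(grid) -> ZipResult:
    """ZIP synergy scoring of a two-drug inhibition grid.

    Single-agent margins are fitted with a logistic rising from 0 to 1; each
    interior row (drug A at fixed dose of B) and column (B at fixed A) is
    fitted with a logistic whose dose-0 asymptote is pinned at the fitted
    single-agent effect of the other drug.  Per interior cell the delta is the
    mean of the two fitted combination effects minus the Bliss expectation
    ``y_a + y_b - y_a * y_b`` of the fitted margins, x100.  Rows/columns whose
    fit fails are excluded and counted.
    """
    doses_a, doses_b, inhib = grid.doses_a, grid.doses_b, grid.inhibition
    if (doses_a.size - 1) < 3 or (doses_b.size - 1) < 3:
        raise ValueError("need >= 3 nonzero doses per drug for ZIP scoring")

    fit_a = _fit_logistic(doses_a, inhib[:, 0])
    fit_b = _fit_logistic(doses_b, inhib[0, :])
    if fit_a is None or fit_b is None:
        raise ValueError("single-agent margin fit failed")
    ya = _logistic_inhibition(doses_a, *fit_a)   # fitted A effect per row dose
    yb = _logistic_inhibition(doses_b, *fit_b)   # fitted B effect per col dose

    na, nb = doses_a.size, doses_b.size
    row_fit = np.full((na, nb), np.nan)   # A varies within a row (fixed B)
    col_fit = np.full((na, nb), np.nan)
    for j in range(1, nb):
        fit = _fit_logistic(doses_a[1:], inhib[1:, j], floor=yb[j])
        if fit is not None:
            row_fit[1:, j] = _logistic_inhibition(doses_a[1:], *fit, floor=yb[j])
    for i in range(1, na):
        fit = _fit_logistic(doses_b[1:], inhib[i, 1:], floor=ya[i])
        if fit is not None:
            col_fit[i, 1:] = _logistic_inhibition(doses_b[1:], *fit, floor=ya[i])

    bliss = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    fitted = 0.5 * (row_fit + col_fit)
    delta = np.full((na, nb), np.nan)
    interior = np.zeros((na, nb), dtype=bool)
    interior[1:, 1:] = True
    ok = interior & np.isfinite(fitted)
    delta[ok] = 100.0 * (fitted[ok] - bliss[ok])
    n_excluded = int(interior.sum() - ok.sum())
    if n_excluded:
        log.warning("ZIP: excluded %d interior cells with failed row/column fits",
                    n_excluded)
    if ok.sum() == 0:
        raise ValueError("no interior cell could be scored")
    mean_delta = float(np.nanmean(delta[ok]))
    return ZipResult(doses_a, doses_b, delta, mean_delta, classify_zip(mean_delta),
                     int(ok.sum()), n_excluded)


def combination_index_grid(grid, fit_a: MedianEffectFit, fit_b: MedianEffectFit):
    """Per-interior-cell Chou-Talalay CI from the observed fa of a dose grid.

    Cells with fa at exactly 0 or 1 (CI undefined) are returned as NaN.
    Supports non-constant-ratio designs: every measured combination cell is
    scored at its own observed effect level.
    """
    na, nb = grid.doses_a.size, grid.doses_b.size
    ci = np.full((na, nb), np.nan)
    for i in range(1, na):
        for j in range(1, nb):
            fa = grid.inhibition[i, j]
            if 0.0 < fa < 1.0:
                ci[i, j] = combination_index(grid.doses_a[i], grid.doses_b[j],
                                             fa, fit_a, fit_b)
    return ci
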