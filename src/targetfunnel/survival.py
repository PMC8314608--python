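"""Stage 2 of the funnel: Kaplan-Meier estimation, two-group log-rank
(Mantel-Haenszel) testing, percentile / IRS stratification, Bonferroni
control, and the per-gene expression-stratified survival screen.

Conventions fixed here (and relied on by the screen):

* ties of events and censorings at the same time: events are processed first
  (the censored subjects are still at risk at that time);
* "high" expression means strictly greater than the interpolated empirical
  quantile; ties at the cutoff go to the low group;
* a gene passes the screen only if its Bonferroni-adjusted p is below alpha
  AND the high-expression group has worse survival (more observed than
  expected events);
* Bonferroni m is the number of genes actually tested — candidates missing
  from the survival dataset (or that cannot be stratified) are reported as
  untested, not failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import SurvivalCohort

log = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "km_estimate",
    "LogRankResult",
    "logrank_test",
    "stratify_by_quantile",
    "stratify_by_irs",
    "bonferroni_adjust",
    "run_survival_screen",
]


@dataclass
class KMCurve:
    """Product-limit estimate: distinct event times, S(t), and per-time
    at-risk / event counts."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


def _validate_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if times.shape != events.shape:
        raise ValueError("times and events must have matching shapes")
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise ValueError("times must be finite and > 0")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times.

    Without censoring this reduces to 1 minus the empirical CDF.
    """
    times, events = _validate_times_events(times, events)
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first          # events first: censored same-time stay at risk
    d = np.add.reduceat(e.astype(np.int64), first)
    keep = d > 0
    if not keep.any():
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int),
                       np.empty(0, dtype=int))
    n_i, d_i = n_at_risk[keep], d[keep]
    surv = np.cumprod(1.0 - d_i / n_i)
    return KMCurve(uniq[keep], surv, n_i, d_i)


@dataclass
class LogRankResult:
    """Two-group log-rank (Mantel-Haenszel) chi-square with per-group O/E.

    ``direction`` names the group with worse survival (observed > expected
    events), or None when O == E.
    """

    statistic: float
    p_value: float
    observed: dict
    expected: dict
    direction: object


def _logrank_core(times: np.ndarray, events: np.ndarray, in_g1: np.ndarray):
    """Return (O1, E1, V) summed over distinct event times.

    At each event time t: E1 += d * n1/n, V += d*(n1/n)*(1-n1/n)*(n-d)/(n-1)
    with the variance term contributing 0 when n == 1.
    """
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    e = events[order]
    g = in_g1[order]
    uniq, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first
    d_tot = np.add.reduceat(e.astype(np.float64), first)
    d1 = np.add.reduceat((e & g).astype(np.float64), first)
    g_suffix = np.concatenate([np.cumsum(g[::-1].astype(np.int64))[::-1], [0]])
    n1 = g_suffix[first].astype(np.float64)

    mask = d_tot > 0
    n_t, d_t = n_at_risk[mask].astype(np.float64), d_tot[mask]
    n1_t, d1_t = n1[mask], d1[mask]
    O1 = float(d1_t.sum())
    E1 = float((d_t * n1_t / n_t).sum())
    frac = n1_t / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d_t * frac * (1.0 - frac) * (n_t - d_t) / (n_t - 1.0)
    v = np.where(n_t > 1.0, v, 0.0)
    return O1, E1, float(v.sum()), float(d_t.sum())


def logrank_test(group_labels, times, events) -> LogRankResult:
    """Two-group log-rank test; labels may be any two distinct values.

    With zero total events (or zero variance) the statistic is 0 and p = 1.
    """
    times, events = _validate_times_events(times, events)
    labels = np.asarray(group_labels)
    if labels.shape != times.shape:
        raise ValueError("group_labels must match times in shape")
    uniq_labels = sorted(pd.unique(labels).tolist(), key=str)
    if len(uniq_labels) != 2:
        raise ValueError(f"exactly 2 non-empty groups required, got {uniq_labels}")
    in_g1 = labels == uniq_labels[0]
    O1, E1, V, d_total = _logrank_core(times, events, in_g1)
    O_total = float(events.sum())
    observed = {uniq_labels[0]: O1, uniq_labels[1]: O_total - O1}
    expected = {uniq_labels[0]: E1, uniq_labels[1]: O_total - E1}
    if d_total == 0 or V <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = (O1 - E1) ** 2 / V
        p = float(special.chdtrc(1, stat))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    if O1 > E1:
        direction = uniq_labels[0]
    elif O1 < E1:
        direction = uniq_labels[1]
    else:
        direction = None
    return LogRankResult(float(stat), float(p), observed, expected, direction)


def stratify_by_quantile(values, percentile: float) -> np.ndarray:
    """Label subjects 'high' (strictly above the interpolated empirical
    quantile) or 'low'; errors if either group would be empty."""
    values = np.asarray(values, dtype=float)
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    if values.size < 2:
        raise ValueError("need >= 2 subjects to stratify")
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise ValueError("cannot stratify: all values identical")
    cutoff = np.quantile(values, percentile)  # linear interpolation
    high = values > cutoff
    if high.all() or not high.any():
        raise ValueError("stratification produced an empty group")
    return np.where(high, "high", "low")


def stratify_by_irs(irs_values, low_max: int = 2) -> np.ndarray:
    """Dichotomize immunoreactive scores: low iff IRS <= low_max (default 2,
    i.e. low IRS <= 2, high IRS > 2)."""
    irs = np.asarray(irs_values)
    if irs.size == 0:
        raise ValueError("no IRS values")
    vals = irs.astype(float)
    if np.any((vals < 0) | (vals > 12) | (vals != np.round(vals))):
        raise ValueError("IRS values must be integers in 0-12")
    return np.where(vals <= low_max, "low", "high")


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Multiply each p by the number of tests (default: len(p)), cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m is None else int(m)
    return np.minimum(1.0, p * m)


def _scan_grid(policy):
    """Normalize a percentile policy: a float is a fixed cutoff, a sequence is
    a scan grid (per gene, the smallest raw p over the grid is reported)."""
    if np.isscalar(policy):
        return [float(policy)], False
    grid = [float(q) for q in policy]
    if not grid:
        raise ValueError("empty percentile grid")
    return grid, True


def run_survival_screen(candidates, cohort: SurvivalCohort,
                        percentile=0.78, alpha: float = 0.05) -> pd.DataFrame:
    """Expression-stratified log-rank screen over candidate genes.

    Per gene: stratify the cohort at the fixed percentile (default the 78th)
    or, when ``percentile`` is a grid, at the grid point minimizing the raw p
    (no within-gene correction across grid points; the induced optimism is
    recorded in the result's ``attrs``).  Bonferroni across the m genes
    actually tested; passes iff adjusted_p < alpha and the high group is
    worse.  Candidates absent from the cohort's expression matrix (or
    unstratifiable) are reported with ``tested = False``.

    Returns a DataFrame with columns gene_id, tested, cutoff_percentile,
    raw_p, adjusted_p, direction, passes — tested genes sorted by adjusted_p.
    """
    candidates = list(candidates)
    if cohort.expression is None:
        raise ValueError("cohort carries no expression data")
    grid, scanning = _scan_grid(percentile)
    times, events = cohort.times, cohort.events
    expr = cohort.expression
    patient_order = cohort.table.index

    rows = []
    for gene in candidates:
        if gene not in expr.index:
            rows.append((gene, False, np.nan, np.nan, np.nan, None, False))
            continue
        vals = expr.loc[gene].reindex(patient_order).to_numpy(dtype=float)
        best = None
        for q in grid:
            try:
                labels = stratify_by_quantile(vals, q)
            except ValueError:
                continue
            res = logrank_test(labels, times, events)
            if best is None or res.p_value < best[1].p_value:
                best = (q, res)
        if best is None:
            rows.append((gene, False, np.nan, np.nan, np.nan, None, False))
            continue
        q, res = best
        rows.append((gene, True, q, res.p_value, np.nan, res.direction, False))

    df = pd.DataFrame(rows, columns=["gene_id", "tested", "cutoff_percentile",
                                     "raw_p", "adjusted_p", "direction", "passes"])
    tested = df["tested"].to_numpy()
    m = int(tested.sum())
    if m:
        df.loc[tested, "adjusted_p"] = bonferroni_adjust(
            df.loc[tested, "raw_p"].to_numpy(), m=m)
        df["passes"] = tested & (df["adjusted_p"] < alpha) & (df["direction"] == "high")
    n_untested = len(df) - m
    if n_untested:
        log.warning("survival screen: %d candidate(s) untested (no coverage or "
                    "unstratifiable)", n_untested)
    df = df.sort_values(["tested", "adjusted_p", "gene_id"],
                        ascending=[False, True, True], kind="mergesort",
                        na_position="last").reset_index(drop=True)
    df.attrs["m_tested"] = m
    df.attrs["alpha"] = alpha
    df.attrs["percentile_policy"] = ("scan" if scanning else "fixed", grid)
    if scanning:
        df.attrs["note"] = ("scan mode reports the minimum raw p over the "
                            "percentile grid with no within-gene correction; "
                            "raw p-values are optimistic")
    return df
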