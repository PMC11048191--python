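"""Viability normalisation, 4PL dose-response fitting and IC50 linkage.

The dose-response model is the four-parameter logistic on log-dose,

    r(d) = bottom + (top - bottom) / (1 + (d / ic50)**hill),

with ``hill > 0`` describing inhibition (response falls towards ``bottom``
at high dose).  IC50 is the concentration at the curve midpoint.  Fitting is
bounded least squares (0 <= bottom, 0 <= span = top - bottom) on the log10
concentration axis with a grid of starts over midpoint location and slope
sign; profiles that never leave the top plateau are flagged unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "FourPLFit",
    "fourpl",
    "normalize_viability",
    "fit_4pl",
    "correlate_sensitivity",
]


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    ic50_se: Optional[float]
    rss: float
    converged: bool
    identifiable: bool
    note: str = ""


def fourpl(d, bottom: float, top: float, hill: float, ic50: float):
    """Four-parameter logistic response at dose(s) ``d``."""
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def normalize_viability(raw_by_time: Mapping[float, Sequence[float]]) -> pd.DataFrame:
    """Relative viability, normalised per replicate to the 0 h reading.

    ``raw_by_time`` maps time (hours) to per-replicate raw fluorescence.
    Returns a tidy frame with columns ``time_h, replicate, raw, relative``.
    Already-normalised input (all 0 h readings equal to 1) is a fixed point.
    """
    times = sorted(raw_by_time)
    if not times or times[0] != 0:
        raise ValueError("time 0 reading required for normalization")
    base = np.asarray(list(raw_by_time[0]), dtype=float)
    if np.any(base <= 0):
        raise ValueError("0 h readings must be positive")
    rows = []
    for t in times:
        vals = np.asarray(list(raw_by_time[t]), dtype=float)
        if vals.shape != base.shape:
            raise ValueError("replicate count must be constant across times")
        if np.any(vals < 0):
            raise ValueError("raw fluorescence must be >= 0")
        for rep, (raw, rel) in enumerate(zip(vals, vals / base)):
            rows.append(dict(time_h=t, replicate=rep, raw=raw, relative=rel))
    return pd.DataFrame(rows, columns=["time_h", "replicate", "raw", "relative"])


def _fit_once(x, y, theta0, bounds):
    return least_squares(
        lambda th: th[0] + th[1] / (1.0 + 10.0 ** (th[2] * (x - th[3]))) - y,
        theta0,
        bounds=bounds,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit returning IC50 with an approximate SE.

    Requires at least 5 distinct positive doses.  Multi-start over midpoint
    location (log-dose quartiles) and slope sign; the start with the lowest
    residual sum of squares wins.  A fit whose midpoint lies outside the
    dosed range or whose span is negligible against the data spread is
    flagged ``identifiable=False`` (IC50 then only bounds the true value).
    """
    d = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must align")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(d).size < 5:
        raise ValueError("need at least 5 distinct doses")

    x = np.log10(d)
    ymin, ymax = float(y.min()), float(y.max())
    span0 = max(ymax - ymin, 1e-12)
    lo = np.array([0.0, 0.0, -np.inf, x.min() - 3.0])
    hi = np.array([np.inf, np.inf, np.inf, x.max() + 3.0])

    best = None
    qs = np.percentile(x, [25, 50, 75])
    for p0 in qs:
        for hill0 in (1.0, -1.0, 3.0, -3.0):
            theta0 = np.array([max(ymin, 0.0), span0, hill0, p0])
            theta0 = np.clip(theta0, lo, hi)
            try:
                res = _fit_once(x, y, theta0, (lo, hi))
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    if best is None or not best.success:
        return FourPLFit(
            bottom=np.nan, top=np.nan, hill=np.nan, ic50=np.nan,
            ic50_se=None, rss=np.nan, converged=False, identifiable=False,
            note="no start converged",
        )
    bottom, span, hill, p = best.x
    top = bottom + span
    rss = float(2.0 * best.cost)
    ic50 = float(10.0 ** p)

    # identifiability: the transition must occur inside the dosed range and
    # the span must be resolvable against the residual scale
    dof = max(y.size - 4, 1)
    sigma = np.sqrt(rss / dof)
    identifiable = bool(
        (x.min() - 0.5 <= p <= x.max() + 0.5)
        and span > max(3.0 * sigma, 1e-6 * max(abs(ymax), 1.0))
        and abs(hill) > 1e-6
    )
    note = "" if identifiable else "flat or truncated profile; ic50 is a bound"

    ic50_se = None
    try:
        J = best.jac
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se_p = float(np.sqrt(cov[3, 3]))
        ic50_se = float(np.log(10.0) * ic50 * se_p)
    except np.linalg.LinAlgError:
        pass

    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        hill=float(hill),
        ic50=ic50,
        ic50_se=ic50_se,
        rss=rss,
        converged=True,
        identifiable=identifiable,
        note=note,
    )


def correlate_sensitivity(
    ic50_by_line: Mapping[str, float],
    nonresponder_frac_by_line: Mapping[str, float],
) -> Tuple[float, int, Optional[float]]:
    """Spearman rank correlation of IC50 against the non-responder fraction.

    Returns ``(rho, n, p)``; the p-value is omitted (None) below n = 5,
    where the rank-permutation null is too coarse to be meaningful.
    """
    lines = sorted(set(ic50_by_line) & set(nonresponder_frac_by_line))
    if len(lines) < 3:
        raise ValueError("need at least 3 paired lines")
    a = np.array([ic50_by_line[l] for l in lines], dtype=float)
    b = np.array([nonresponder_frac_by_line[l] for l in lines], dtype=float)
    res = stats.spearmanr(a, b)
    rho = float(res.statistic)
    p = float(res.pvalue) if len(lines) >= 5 else None
    return rho, len(lines), p
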