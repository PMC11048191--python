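"""Per-cell response classification, heterogeneity summaries and statistics.

A tracked cell's trajectory is the pair of background-subtracted intensities
at baseline and 48 h post-treatment.  Its status is *increased* iff the
post-treatment intensity strictly exceeds baseline (ties, possible on
integer counts, count as decreased — the conservative call for an
inhibition assay).  Intensities are additionally compared against the limit
of detection: a cell below the LOD at both timepoints never rose out of the
background "gray zone" and is excluded from the response fractions; a cell
above at baseline but below after treatment is the "no detectable signal"
phenotype.  Bulk AR activity sums the above-LOD intensities per well and is
expressed relative to the DHT-only control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import LOD

__all__ = [
    "CellTrajectory",
    "ResponseSummary",
    "BulkActivity",
    "classify_cell",
    "summarize_responses",
    "bulk_activity",
    "stability_test",
    "compare_conditions",
    "p_to_stars",
]


@dataclass(frozen=True)
class CellTrajectory:
    id_t0: int
    id_t1: int
    intensity_t0: float
    intensity_t1: float
    status: Optional[str]  # "increased" | "decreased" | None (unclassifiable)
    below_lod_t0: bool
    below_lod_t1: bool

    @property
    def classifiable(self) -> bool:
        return self.status is not None


@dataclass(frozen=True)
class ResponseSummary:
    condition: str
    n_tracked: int
    n_classifiable: int
    n_increased: int
    n_decreased: int
    n_no_signal: int  # decreased cells below LOD after treatment
    frac_increased: Optional[float]
    frac_decreased: Optional[float]
    frac_no_signal_among_decreased: Optional[float]


@dataclass(frozen=True)
class BulkActivity:
    condition: str
    total_intensity: float  # mean per-well sum of above-LOD intensities
    relative_pct: float


def classify_cell(
    intensity_t0: float,
    intensity_t1: float,
    lod: LOD,
    id_t0: int = -1,
    id_t1: int = -1,
) -> CellTrajectory:
    """Classify one tracked cell's trajectory against the LOD.

    Status is increased iff ``intensity_t1 > intensity_t0`` (strict); cells
    below the LOD at both timepoints are unclassifiable (status None) but
    retained in the output.
    """
    if not (np.isfinite(intensity_t0) and np.isfinite(intensity_t1)):
        raise ValueError("intensities must be finite")
    b0 = intensity_t0 < lod.value
    b1 = intensity_t1 < lod.value
    if b0 and b1:
        status = None
    elif intensity_t1 > intensity_t0:
        status = "increased"
    else:
        status = "decreased"
    return CellTrajectory(
        id_t0=id_t0,
        id_t1=id_t1,
        intensity_t0=float(intensity_t0),
        intensity_t1=float(intensity_t1),
        status=status,
        below_lod_t0=bool(b0),
        below_lod_t1=bool(b1),
    )


def summarize_responses(
    trajectories: Sequence[CellTrajectory], condition: str = ""
) -> ResponseSummary:
    """Population response fractions over classifiable tracked cells."""
    n_tracked = len(trajectories)
    cls = [t for t in trajectories if t.classifiable]
    n_inc = sum(1 for t in cls if t.status == "increased")
    n_dec = sum(1 for t in cls if t.status == "decreased")
    n_nosig = sum(1 for t in cls if t.status == "decreased" and t.below_lod_t1)
    n_cls = len(cls)
    return ResponseSummary(
        condition=condition,
        n_tracked=n_tracked,
        n_classifiable=n_cls,
        n_increased=n_inc,
        n_decreased=n_dec,
        n_no_signal=n_nosig,
        frac_increased=n_inc / n_cls if n_cls else None,
        frac_decreased=n_dec / n_cls if n_cls else None,
        frac_no_signal_among_decreased=n_nosig / n_dec if n_dec else None,
    )


def bulk_activity(
    intensities_by_well: Mapping[str, Mapping[str, Sequence[float]]],
    lod: LOD,
    reference_condition: str,
) -> List[BulkActivity]:
    """Bulk AR activity per condition, relative to the reference condition.

    ``intensities_by_well`` maps condition -> well -> per-cell intensities.
    Per condition the above-LOD ("positive cell") intensities are summed per
    replicate well and averaged across wells; the result is expressed as a
    percentage of the reference condition's value, which is 100 by
    construction.
    """
    if reference_condition not in intensities_by_well:
        raise KeyError(f"reference condition {reference_condition!r} missing")

    def per_condition_total(wells: Mapping[str, Sequence[float]]) -> float:
        sums = []
        for well, vals in wells.items():
            arr = np.asarray(list(vals), dtype=float)
            sums.append(float(arr[arr > lod.value].sum()) if arr.size else 0.0)
        return float(np.mean(sums)) if sums else 0.0

    ref_total = per_condition_total(intensities_by_well[reference_condition])
    if ref_total <= 0:
        raise ValueError("reference condition has no positive signal")
    out = []
    for cond, wells in intensities_by_well.items():
        total = per_condition_total(wells)
        out.append(
            BulkActivity(
                condition=cond,
                total_intensity=total,
                relative_pct=100.0 * total / ref_total,
            )
        )
    return out


def stability_test(
    intensities_start: Sequence[float], intensities_end: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-cell intensities.

    Used to ask whether the signal at the end of the substrate time course
    differs from the start.  All-zero differences return p = 1.
    """
    a = np.asarray(list(intensities_start), dtype=float)
    b = np.asarray(list(intensities_end), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 6:
        raise ValueError("need at least 6 paired observations")
    if np.allclose(a, b):
        return 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return float(res.pvalue)


def p_to_stars(p: float) -> str:
    """Significance stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ValueError(f"invalid p-value {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_conditions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> Tuple[float, str]:
    """Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired) comparison.

    Returns the two-sided p-value and its significance stars.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        if np.allclose(a, b):
            return 1.0, "ns"
        p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, p_to_stars(p)


def trajectories_to_frame(trajectories: Sequence[CellTrajectory]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                id_t0=t.id_t0,
                id_t1=t.id_t1,
                intensity_t0=t.intensity_t0,
                intensity_t1=t.intensity_t1,
                status=t.status if t.status is not None else "unclassifiable",
                below_lod_t0=t.below_lod_t0,
                below_lod_t1=t.below_lod_t1,
            )
            for t in trajectories
        ],
        columns=[
            "id_t0", "id_t1", "intensity_t0", "intensity_t1",
            "status", "below_lod_t0", "below_lod_t1",
        ],
    )
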