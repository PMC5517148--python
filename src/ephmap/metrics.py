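"""Quantitative summaries of simulation results.

All metrics are pure functions of a :class:`~ephmap.model.SimulationResult`.
Sign convention for topography: temporal origin mapping to anterior target
(small x) counts as positive, i.e. the ideal map is ``x = W (1 - u)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .model import SimulationResult

__all__ = [
    "MappingSummary",
    "mapping_summary",
    "stopping_fraction",
    "entry_fraction",
    "knockin_displacement",
]


@dataclass(frozen=True)
class MappingSummary:
    origin_u: np.ndarray
    final_x: np.ndarray
    rank_correlation: float          # NaN when n < 3
    diagonal_fraction: float
    coverage_span: float
    tolerance: float


def _mobile_subset(result: SimulationResult) -> np.ndarray:
    return np.asarray(result.mobile, dtype=bool)


def mapping_summary(
    result: SimulationResult,
    tolerance: float = 0.1,
    field_width: Optional[float] = None,
) -> MappingSummary:
    """Topographic order of the final map.

    ``rank_correlation`` is the Spearman correlation between retinal origin
    and final anterior-posterior position, signed so that the correct
    temporal-to-anterior polarity is positive.  ``diagonal_fraction`` is
    the share of terminals within ``tolerance`` (in normalized field
    units) of the ideal diagonal; ``coverage_span`` the spanned fraction
    of the field width.  Frozen resident terminals are excluded.
    """
    sel = _mobile_subset(result)
    u = result.origin_u[sel]
    x = result.final_x[sel]
    if field_width is None:
        field_width = result.analysis_hints.get(
            "field_width", float(np.ceil(x.max())) if x.size else 1.0
        )
    W = float(field_width)
    if u.size >= 3 and np.ptp(x) > 0 and np.ptp(u) > 0:
        rho = float(stats.spearmanr(u, -x).statistic)
    else:
        rho = float("nan")
    ideal = 1.0 - u
    dev = np.abs(x / W - ideal)
    diag = float(np.mean(dev <= tolerance)) if u.size else float("nan")
    span = float((x.max() - x.min()) / W) if u.size else float("nan")
    return MappingSummary(
        origin_u=u,
        final_x=x,
        rank_correlation=rho,
        diagonal_fraction=diag,
        coverage_span=span,
        tolerance=tolerance,
    )


def stopping_fraction(
    result: SimulationResult,
    second_field_start: Optional[float] = None,
    penetration: float = 2.0,
) -> float:
    """Fraction of terminals that never invaded the field past a boundary.

    A terminal counts as stopped when its maximum x over the whole run
    never exceeded ``second_field_start + penetration`` (it never entered
    the field's leading ``penetration`` units).
    """
    if second_field_start is None:
        second_field_start = result.analysis_hints["second_field_start"]
    sel = _mobile_subset(result)
    return float(np.mean(result.max_x[sel] < second_field_start + penetration))


def entry_fraction(
    result: SimulationResult,
    target_start: Optional[float] = None,
) -> float:
    """Fraction of terminals whose final x lies on the target field."""
    if target_start is None:
        target_start = result.analysis_hints["target_start"]
    sel = _mobile_subset(result)
    x = result.final_x[sel]
    if x.size == 0:
        raise ValueError("no mobile terminals to evaluate")
    return float(np.mean(x >= target_start))


def knockin_displacement(
    result: SimulationResult,
    field_width: Optional[float] = None,
) -> Tuple[float, float]:
    """Mean signed final-x deviation from the unperturbed ideal diagonal.

    Returns ``(mean_shift_wt, mean_shift_ki)``; positive = posterior.
    Requires terminals labelled ``wt`` / ``ki``.
    """
    labels = np.asarray(result.labels)
    if not set(np.unique(labels)) <= {"wt", "ki"}:
        raise ValueError("result lacks wt/ki terminal labels")
    if field_width is None:
        field_width = result.analysis_hints.get(
            "field_width", float(np.ceil(result.positions[..., 0].max()))
        )
    W = float(field_width)
    ideal = W * (1.0 - result.origin_u)
    dev = result.final_x - ideal
    wt = float(np.mean(dev[labels == "wt"]))
    ki_mask = labels == "ki"
    ki = float(np.mean(dev[ki_mask])) if ki_mask.any() else float("nan")
    return wt, ki
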