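"""Plate-level screening statistics: normalization, hit calling, Z'-factor.

Activity is expressed relative to the plate's own controls: the positive
control (a saturating nuclear-export block, e.g. 4 nM leptomycin B) defines
100% and the vehicle control defines 0%. A compound is a hit when its
normalized activity strictly exceeds the hit threshold (default 60%).
Plate quality is the Z'-factor of Zhang et al.:

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|

Z' near 1 indicates a wide, reliable screening window; Z' <= 0 a failed
plate. No multiple-testing correction is applied: hit calling is a fixed
activity cutoff, not a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

HIT_THRESHOLD = 60.0  # percent of positive-control activity


class DegenerateControlsError(ValueError):
    """Positive and negative control means coincide: no screening window."""


@dataclass(frozen=True)
class ControlStats:
    """Control-well statistics in pct-translocated units."""

    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    n_pos: int
    n_neg: int
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        if self.sd_pos < 0 or self.sd_neg < 0:
            raise ValueError("control sds must be >= 0")

    @classmethod
    def from_values(
        cls,
        positives: Iterable[float],
        negatives: Iterable[float],
        plate_id: str = "plate1",
    ) -> "ControlStats":
        pos = np.asarray(list(positives), dtype=float)
        neg = np.asarray(list(negatives), dtype=float)
        if pos.size < 2 or neg.size < 2:
            raise ValueError("need at least 2 positive and 2 negative control wells")
        return cls(
            mean_pos=float(pos.mean()),
            sd_pos=float(pos.std(ddof=1)),
            mean_neg=float(neg.mean()),
            sd_neg=float(neg.std(ddof=1)),
            n_pos=int(pos.size),
            n_neg=int(neg.size),
            plate_id=plate_id,
        )


@dataclass(frozen=True)
class HitCall:
    well: str
    compound: str
    activity_pct: float
    is_hit: bool


def normalize_activity(well_pct: float, controls: ControlStats) -> float:
    """Percent translocated -> percent-of-positive-control activity.

    Affine in ``well_pct``: the negative-control mean maps to 0 and the
    positive-control mean to 100. Values outside [0, 100] are legitimate.
    """
    window = controls.mean_pos - controls.mean_neg
    if window == 0:
        raise DegenerateControlsError(
            f"plate {controls.plate_id}: positive and negative control means are equal"
        )
    return 100.0 * (well_pct - controls.mean_neg) / window


def call_hits(
    activities: Mapping[str, tuple[str, float]],
    hit_threshold: float = HIT_THRESHOLD,
) -> list[HitCall]:
    """Call hits from ``{well: (compound, activity_pct)}``.

    A hit strictly exceeds the threshold (activity == threshold is not a
    hit). Output is sorted by activity descending, ties by well id.
    """
    calls = [
        HitCall(well, compound, float(act), float(act) > hit_threshold)
        for well, (compound, act) in activities.items()
    ]
    if any(not np.isfinite(c.activity_pct) for c in calls):
        raise ValueError("activities must be finite")
    return sorted(calls, key=lambda c: (-c.activity_pct, c.well))


def zprime(controls: ControlStats, bracket: str = "zhang") -> float:
    """Z'-factor of a plate's control separation.

    ``bracket="zhang"`` is the standard form
    ``1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|`` (noiseless controls give
    exactly 1; values can go negative on a failed plate). The alternative
    ``bracket="as-printed"`` reproduces a commonly mis-typeset variant in
    which only the negative-control term is divided by the control
    separation; it is provided for comparison only.
    """
    if controls.n_pos < 2 or controls.n_neg < 2:
        raise ValueError("Z' needs >= 2 wells per control")
    window = controls.mean_pos - controls.mean_neg
    if window == 0:
        raise DegenerateControlsError(
            f"plate {controls.plate_id}: positive and negative control means are equal"
        )
    if bracket == "zhang":
        return 1.0 - 3.0 * (controls.sd_pos + controls.sd_neg) / abs(window)
    if bracket == "as-printed":
        return 1.0 - (3.0 * controls.sd_pos + 3.0 * controls.sd_neg / window)
    raise ValueError(f"unknown bracket form {bracket!r}")
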