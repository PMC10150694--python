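"""Deterministic re-implementation of the real-time stimulation controller.

The optogenetic assays pulse a light-activated GPCR at a computed point on
the cell boundary, with assay-specific onset rules:

* competition assays target the left front; continuous/early stimulation
  starts once both fronts have extended at least 2.2 um past the obstacle
  apex, the late variant once both have extended at least 6.6 um;
* reversal assays target the retracting (losing) front; continuous/early
  stimulation starts at the first detected big retraction (cumulative
  retracted area > 7.2 um^2), the late variant once the retracting edge has
  come back to the apex midline.

Early assays deliver exactly 5 pulses; continuous and late assays pulse to
the end of the event.  Pulses repeat every 3 s, the shared imaging and
stimulation interval.  No hardware is driven here: plans are pure data
consumed by the synthetic generator's optional behavioural bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "StimulationPlan",
    "TimelineFrame",
    "Pulse",
    "onset_satisfied",
    "target_point",
    "schedule",
]

_ASSAYS = ("competition_continuous", "competition_early", "competition_late",
           "reversal_continuous", "reversal_early", "reversal_late")


@dataclass
class StimulationPlan:
    assay: str = "competition_continuous"
    pulse_interval: float = 3.0          # s, same as the imaging interval
    n_pulses: int | None = None          # 5 for early assays, else unbounded
    extension_threshold: float = 2.2     # um, continuous/early competition
    late_extension_threshold: float = 6.6   # um, late competition
    big_retraction_threshold: float = 7.2   # um^2, reversal assays
    apex_reach_tolerance: float = 0.21   # um (~1 px), late reversal
    target_angle: float = 0.0            # degrees from motion orientation

    def __post_init__(self) -> None:
        if self.assay not in _ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.n_pulses is None and self.assay.endswith("early"):
            self.n_pulses = 5
        if self.pulse_interval <= 0:
            raise ValueError("pulse_interval must be positive")

    @property
    def is_competition(self) -> bool:
        return self.assay.startswith("competition")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class TimelineFrame:
    """Per-frame state the controller reads in real time."""

    time: float
    extension_left: float = 0.0          # um past the apex
    extension_right: float = 0.0
    cumulative_retraction: float = 0.0   # um^2, losing front
    retracting_side: str | None = None
    retract_edge_apex_distance: float = np.inf   # um
    mask: np.ndarray | None = None
    orientation: tuple[float, float] = (-1.0, 0.0)   # (drow, dcol): "up"
    target_points: dict = field(default_factory=dict)  # side -> (row, col)


@dataclass
class Pulse:
    time: float
    target: tuple[int, int] | None
    side: str


def onset_satisfied(state: TimelineFrame, plan: StimulationPlan) -> bool:
    """Assay-specific trigger rule; all thresholds are inclusive where the
    protocol says 'at least'."""
    a = plan.assay
    if a in ("competition_continuous", "competition_early"):
        thr = plan.extension_threshold
        return (state.extension_left >= thr
                and state.extension_right >= thr)
    if a == "competition_late":
        thr = plan.late_extension_threshold
        return (state.extension_left >= thr
                and state.extension_right >= thr)
    if a in ("reversal_continuous", "reversal_early"):
        return state.cumulative_retraction > plan.big_retraction_threshold
    if a == "reversal_late":
        return state.retract_edge_apex_distance <= plan.apex_reach_tolerance
    raise ValueError(f"unknown assay {a!r}")


def target_point(mask: np.ndarray, reference_orientation,
                 target_angle: float = 0.0) -> tuple[int, int]:
    """Boundary pixel at ``target_angle`` (degrees) about the mask centroid.

    The angle is measured from the unit vector of pre-contact cell motion
    (``reference_orientation``, as (drow, dcol)); 0 degrees points straight
    ahead of the cell.  Ties are broken by smallest row-major index.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    rows, cols = np.nonzero(boundary)
    r0, c0 = ndimage.center_of_mass(mask)
    ref = np.arctan2(reference_orientation[1], reference_orientation[0])
    ang = np.arctan2(cols - c0, rows - r0) - ref - np.deg2rad(target_angle)
    miss = np.abs(np.angle(np.exp(1j * ang)))
    best = np.flatnonzero(miss == miss.min())
    # row-major tie-break
    order = np.lexsort((cols[best], rows[best]))
    k = best[order[0]]
    return int(rows[k]), int(cols[k])


def _frame_target(frame: TimelineFrame, side: str,
                  plan: StimulationPlan) -> tuple[int, int] | None:
    if side in frame.target_points:
        return tuple(frame.target_points[side])
    if frame.mask is not None:
        return target_point(frame.mask, frame.orientation,
                            plan.target_angle)
    return None


def schedule(plan: StimulationPlan, timeline) -> list[Pulse]:
    """Pulse schedule for an event timeline (list of TimelineFrame).

    The first pulse fires at the first frame satisfying the onset rule and
    pulses repeat every ``pulse_interval``; early assays stop after exactly
    ``n_pulses``.  Each pulse carries the target computed on its own frame:
    the left front for competition assays, the retracting (or previously
    retracting) front for reversal assays.  An onset rule never satisfied
    yields an empty schedule.
    """
    pulses: list[Pulse] = []
    next_time: float | None = None
    retract_side_memory: str | None = None
    for frame in timeline:
        if frame.retracting_side is not None:
            retract_side_memory = frame.retracting_side
        if next_time is None:
            if onset_satisfied(frame, plan):
                next_time = frame.time
            else:
                continue
        if plan.n_pulses is not None and len(pulses) >= plan.n_pulses:
            break
        if frame.time + 1e-9 >= next_time:
            side = ("left" if plan.is_competition
                    else (retract_side_memory or "left"))
            pulses.append(Pulse(time=frame.time,
                                target=_frame_target(frame, side, plan),
                                side=side))
            next_time = frame.time + plan.pulse_interval
    return pulses
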