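"""Synthetic decision-making events for cells at a symmetric channel bifurcation.

Real experiments confine fast-migrating neutrophil-like cells in microfluidic
channels that bifurcate around an oval obstacle.  On contact the cell splits
its leading edge into two competing fronts, one per branch; the competition is
resolved when one front starts retracting.  This module fabricates such events
with known ground truth at two tiers:

``image`` tier
    Full movies: per-frame binary cell masks plus fluorescence channels
    (including FRET donor/acceptor pairs with vignetting and photobleaching),
    rendered on an explicit channel geometry.

``feature`` tier
    Per-frame feature vectors drawn directly with the same statistical
    structure (class-dependent asymmetry appearing at a controllable fraction
    of the decision interval), bypassing image rendering.  This is the fast
    path for exercising the time-synchronisation and classification stages.

All randomness flows from a single integer seed; identical parameters give
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "GeneratorParams",
    "FrameRecord",
    "EventMovie",
    "EventLabel",
    "FeatureTrajectory",
    "SyntheticDataset",
    "generate_dataset",
    "generate_fret_pair",
    "write_image_event",
    "write_feature_dataset",
]


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

@dataclass
class ChannelGeometry:
    """Bifurcating-channel geometry on a pixel grid.

    Image coordinates are 0-based (row, column); the channel axis points "up"
    (towards decreasing row index) into the obstacle.  The cell migrates up a
    straight stem channel, meets the bottom tip ("apex") of an oval obstacle
    and splits into a left and a right branch that wrap around the obstacle.

    Physical fields are in micrometres; ``pixel_size`` converts to pixels.
    ``channel_height`` is metadata only (cells are confined to a quasi-2D
    cross-section).
    """

    pixel_size: float = 0.21          # um per pixel
    channel_width: float = 6.0        # um, stem channel
    channel_height: float = 3.0       # um, metadata only
    branch_width_left: float = 4.2    # um
    branch_width_right: float = 4.2   # um
    image_shape: tuple[int, int] = (180, 150)
    obstacle_center: tuple[float, float] = (80.0, 75.0)   # (row, col) px
    obstacle_semiaxes: tuple[float, float] = (5.0, 3.0)   # (along, across) um
    _n_midline: int = 160

    def __post_init__(self) -> None:
        if self.channel_width <= 0 or self.branch_width_left <= 0 \
                or self.branch_width_right <= 0:
            raise ValueError("channel and branch widths must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self._cache: dict = {}

    # -- basic derived quantities ------------------------------------------

    @property
    def semi_px(self) -> tuple[float, float]:
        a, b = self.obstacle_semiaxes
        return a / self.pixel_size, b / self.pixel_size

    @property
    def apex(self) -> tuple[float, float]:
        """Bottom tip of the obstacle, (row, col) in pixels."""
        a_px, _ = self.semi_px
        rc, cc = self.obstacle_center
        return rc + a_px, cc

    def branch_width(self, side: str) -> float:
        if side == "left":
            return self.branch_width_left
        if side == "right":
            return self.branch_width_right
        raise ValueError(f"unknown side {side!r}")

    # -- midlines ----------------------------------------------------------

    def midline(self, side: str) -> np.ndarray:
        """Branch midline polyline, (n, 2) float array of (row, col) pixels.

        Starts at the obstacle apex and wraps around the obstacle at half a
        branch width from its boundary.
        """
        key = ("midline", side)
        if key not in self._cache:
            sgn = 1.0 if side == "left" else -1.0
            a_px, b_px = self.semi_px
            rc, cc = self.obstacle_center
            off_full = 0.5 * self.branch_width(side) / self.pixel_size
            phi = np.linspace(0.0, 0.95 * np.pi, self._n_midline)
            # offset from the obstacle grows from 0 at the apex (where the
            # cell front splits) to half a branch width within the branch
            off = off_full * np.clip(phi / 0.5, 0.0, 1.0)
            rows = rc + a_px * np.cos(phi)
            cols = cc - sgn * b_px * np.sin(phi)
            nr = np.cos(phi) / a_px
            ncol = -sgn * np.sin(phi) / b_px
            norm = np.hypot(nr, ncol)
            self._cache[key] = np.column_stack(
                [rows + off * nr / norm, cols + off * ncol / norm])
        return self._cache[key]

    def midline_arclength(self, side: str) -> np.ndarray:
        """Cumulative arc length (um) along the midline, 0 at the apex."""
        key = ("arc", side)
        if key not in self._cache:
            m = self.midline(side)
            steps = np.hypot(*np.diff(m, axis=0).T) * self.pixel_size
            self._cache[key] = np.concatenate([[0.0], np.cumsum(steps)])
        return self._cache[key]

    # -- rasterised regions ------------------------------------------------

    def obstacle_mask(self) -> np.ndarray:
        key = "obstacle"
        if key not in self._cache:
            a_px, b_px = self.semi_px
            rc, cc = self.obstacle_center
            rr, cols = np.mgrid[0:self.image_shape[0], 0:self.image_shape[1]]
            self._cache[key] = ((rr - rc) / a_px) ** 2 \
                + ((cols - cc) / b_px) ** 2 <= 1.0
        return self._cache[key]

    def _regions(self):
        """Per-pixel region label and progress coordinate.

        Returns (label, s): ``label`` is 0 outside the channel, 1 stem,
        2 left branch, 3 right branch; ``s`` is the progress coordinate in
        micrometres (negative below the apex in the stem, arc length past the
        apex in a branch).
        """
        key = "regions"
        if key not in self._cache:
            h, w = self.image_shape
            rr, cols = np.mgrid[0:h, 0:w]
            apex_r, apex_c = self.apex
            label = np.zeros((h, w), dtype=np.int8)
            s = np.full((h, w), np.nan)

            stem_hw = 0.5 * self.channel_width / self.pixel_size
            stem = (np.abs(cols - apex_c) <= stem_hw) & (rr >= apex_r - 1)
            label[stem] = 1
            s[stem] = (apex_r - rr[stem]) * self.pixel_size

            obst = self.obstacle_mask()
            pix = np.column_stack([rr.ravel(), cols.ravel()]).astype(float)
            for code, side in ((2, "left"), (3, "right")):
                m = self.midline(side)
                arc = self.midline_arclength(side)
                hw = 0.5 * self.branch_width(side) / self.pixel_size
                # project every pixel onto the polyline segments: distance
                # to the tube and arc coordinate at the projected point
                A, B = m[:-1], m[1:]
                seg = B - A
                seg_len2 = np.maximum((seg ** 2).sum(axis=1), 1e-12)
                t = (((pix[:, None, :] - A[None, :, :]) * seg[None, :, :]
                      ).sum(axis=2) / seg_len2[None, :])
                t = np.clip(t, 0.0, 1.0)
                Q = A[None, :, :] + t[:, :, None] * seg[None, :, :]
                d2 = ((pix[:, None, :] - Q) ** 2).sum(axis=2)
                best = np.argmin(d2, axis=1)
                rows_idx = np.arange(len(pix))
                dist = np.sqrt(d2[rows_idx, best])
                arc_at = (arc[best]
                          + t[rows_idx, best] * (arc[best + 1] - arc[best]))
                inb = (dist.reshape(h, w) <= hw) & ~obst
                # the stem/branch overlap just below the apex stays stem
                inb &= label != 1
                label[inb] = code
                s[inb] = arc_at.reshape(h, w)[inb]
            label[obst] = 0
            s[obst] = np.nan
            self._cache[key] = (label, s)
        return self._cache[key]

    def free_mask(self) -> np.ndarray:
        """All pixels a confined cell may occupy."""
        return self._regions()[0] > 0

    def rasterise_cell(self, rear_s: float, tip_s: float,
                       front_left: float | None = None,
                       front_right: float | None = None) -> np.ndarray:
        """Binary cell mask for the given progress extents (um).

        Before contact pass only ``tip_s`` (< 0); after contact pass both
        branch front positions and the stem is filled up to the apex.
        """
        label, s = self._regions()
        mask = np.zeros(self.image_shape, dtype=bool)
        if front_left is None and front_right is None:
            mask |= (label == 1) & (s >= rear_s) & (s <= tip_s)
        else:
            mask |= (label == 1) & (s >= rear_s) & (s <= 0.5)
            if front_left is not None:
                mask |= (label == 2) & (s <= front_left)
            if front_right is not None:
                mask |= (label == 3) & (s <= front_right)
        # rasterisation of the wrapped branch regions can shed sub-pixel
        # crumbs; a confined cell is one connected component by contract
        from scipy import ndimage as _ndi
        lab, n = _ndi.label(mask, structure=np.ones((3, 3)))
        if n > 1:
            sizes = _ndi.sum_labels(np.ones_like(lab), lab,
                                    np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        return mask

    def max_extension(self, side: str) -> float:
        return float(self.midline_arclength(side)[-1])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_n_midline", None)
        return d


# --------------------------------------------------------------------------
# Parameters and records
# --------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Knobs of the synthetic-event generator.

    ``duration_mean``/``duration_sd`` set the decision-interval distribution
    (population values 45 s +/- 15 s); ``divergence_onset_fraction`` (tau) is
    the fraction of the decision interval at which the class-dependent
    asymmetry appears, and ``effect_size`` its final magnitude in standardized
    (noise-SD) units, growing linearly from onset to the final pre-retraction
    frame.  The asymmetry process of real cells is unobserved; tau and
    effect_size are free knobs, not estimates.
    """

    n_events: int = 100
    seed: int = 0
    frame_interval: float = 3.0       # s
    duration_mean: float = 45.0       # s
    duration_sd: float = 15.0         # s
    divergence_onset_fraction: float = 0.67
    effect_size: float = 1.5          # standardized units
    n_features: int = 696             # feature tier: catalogue size
    n_informative_features: int = 5
    noise_sd: float = 1.0
    bleach_slope: float = 0.0         # fractional signal loss per frame
    gradient_amplitude: float = 0.0   # top-to-bottom FRET vignetting
    stimulation_bias: float = 0.0     # probability offset in [0, 0.5]

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0.0 <= self.divergence_onset_fraction <= 1.0:
            raise ValueError("divergence_onset_fraction must be in [0, 1]")
        if self.duration_sd < 0 or self.noise_sd < 0:
            raise ValueError("duration_sd and noise_sd must be >= 0")
        if not 0.0 <= self.stimulation_bias <= 0.5:
            raise ValueError("stimulation_bias must be in [0, 0.5]")
        if abs(self.gradient_amplitude) > 1:
            raise ValueError("gradient_amplitude magnitude must be <= 1")
        if not 0 < self.n_informative_features <= self.n_features:
            raise ValueError("need 0 < n_informative_features <= n_features")


@dataclass
class FrameRecord:
    """One movie frame: acquisition time, binary mask and named channels."""

    time: float
    mask: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EventMovie:
    event_id: str
    frames: list[FrameRecord]
    geometry: ChannelGeometry
    frame_interval: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("an event needs at least 2 frames")

    def masks(self) -> np.ndarray:
        return np.stack([f.mask for f in self.frames])

    def channel_stack(self, name: str) -> np.ndarray:
        return np.stack([f.channels[name] for f in self.frames])


@dataclass
class EventLabel:
    outcome: str                       # "left" or "right"
    true_divergence_frame: int         # generator ground truth

    def __post_init__(self) -> None:
        if self.outcome not in ("left", "right"):
            raise ValueError("outcome must be 'left' or 'right'")


@dataclass
class FeatureTrajectory:
    """Feature-tier event: raw per-frame feature vectors over the decision."""

    event_id: str
    times: np.ndarray                  # (F,) seconds from contact
    values: np.ndarray                 # (F, n_features)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class SyntheticDataset:
    """Generated events plus the generator's ground truth bookkeeping."""

    events: list[tuple[object, EventLabel]]
    params: GeneratorParams
    tier: str
    informative_features: np.ndarray | None = None
    feature_signs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def labels(self) -> np.ndarray:
        """Binary outcome vector, right = 1 and left = 0."""
        return np.array([1 if lab.outcome == "right" else 0
                         for _, lab in self.events])

    def durations(self) -> np.ndarray:
        """Decision durations (s), contact to retraction initiation."""
        out = []
        for ev, _ in self.events:
            if isinstance(ev, FeatureTrajectory):
                out.append(ev.duration)
            else:
                out.append(ev.decision_duration)  # type: ignore[attr-defined]
        return np.asarray(out)


# --------------------------------------------------------------------------
# Core sampling helpers
# --------------------------------------------------------------------------

def _draw_duration_frames(rng: np.random.Generator,
                          params: GeneratorParams) -> int:
    """Decision duration in whole frames (rounded; redrawn below 2 frames)."""
    while True:
        d = rng.normal(params.duration_mean, params.duration_sd)
        f = int(round(d / params.frame_interval))
        if f >= 1:          # f intervals -> f + 1 >= 2 sampled frames
            return f


def _signal_ramp(n_frames: int, tau: float, effect: float) -> np.ndarray:
    """Class-dependent asymmetry magnitude per decision frame.

    Zero strictly before frame ceil(tau * duration); from that frame it grows
    linearly, reaching ``effect`` at the final pre-retraction frame.
    """
    dur = n_frames - 1                       # frame intervals
    onset = int(np.ceil(tau * dur))
    ramp = np.zeros(n_frames)
    if onset <= dur:
        k = np.arange(onset, n_frames)
        ramp[k] = effect * (k - onset + 1) / (dur - onset + 1)
    return ramp


def _draw_outcome(rng: np.random.Generator, params: GeneratorParams,
                  stimulation: dict | None, onset_frame: int) -> str:
    """Fair coin unless a stimulation pulse lands at/after asymmetry onset."""
    p_right = 0.5
    if stimulation is not None and params.stimulation_bias > 0:
        side = stimulation.get("side", "left")
        pulse_frames = np.asarray(stimulation.get("pulse_frames", ()))
        if pulse_frames.size and np.any(pulse_frames >= onset_frame):
            tilt = params.stimulation_bias
            p_right = 0.5 + (tilt if side == "right" else -tilt)
    return "right" if rng.random() < p_right else "left"


# --------------------------------------------------------------------------
# FRET optics
# --------------------------------------------------------------------------

def generate_fret_pair(truth_ratio_field: np.ndarray,
                       params: GeneratorParams,
                       frame_index: int = 0,
                       mask: np.ndarray | None = None,
                       donor_level: float = 100.0,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Render a (donor, acceptor) image pair from a ground-truth ratio field.

    The raw acceptor/donor ratio equals ``truth * (1 + gradient) * bleach(t)``
    plus shot-like noise, where the gradient is a smooth top-to-bottom
    multiplicative ramp of amplitude ``gradient_amplitude`` (+amp/2 at the top
    row, -amp/2 at the bottom) and bleach is multiplicative-linear in the
    frame index, ``1 - bleach_slope * frame_index`` (``bleach_slope`` is the
    fractional loss per frame).
    """
    truth = np.asarray(truth_ratio_field, dtype=float)
    if mask is None:
        mask = truth > 0
    if np.any(truth[mask] <= 0):
        raise ValueError("truth ratio must be positive inside the mask")
    h, w = truth.shape
    rows = np.arange(h, dtype=float)
    vignette = 1.0 + params.gradient_amplitude * (0.5 - rows / max(h - 1, 1))
    bleach = 1.0 - params.bleach_slope * frame_index
    donor = np.zeros_like(truth)
    donor[mask] = donor_level
    acceptor = donor * truth * vignette[:, None] * bleach
    if rng is not None and params.noise_sd > 0:
        scale = params.noise_sd * np.sqrt(np.maximum(donor_level, 1.0))
        donor = donor + rng.normal(0.0, scale, donor.shape) * mask
        acceptor = acceptor + rng.normal(0.0, scale, acceptor.shape) * mask
        donor = np.clip(donor, 0.0, None)
        acceptor = np.clip(acceptor, 0.0, None)
    return donor, acceptor


# --------------------------------------------------------------------------
# Image-tier event synthesis
# --------------------------------------------------------------------------

_PRE_FRAMES = 3
_POST_FRAMES = 10
_FRONT_SPEED = 0.35        # um per frame, each front during the decision
_REAR_SPEED = 0.25         # um per frame
_APPROACH_SPEED = 0.75     # um per frame before contact
_RETRACT_SPEED = 0.5       # um per frame after retraction initiation
_CELL_LENGTH = 12.0        # um at entry
_BACKGROUND = 10.0
_CYTO_LEVEL = 60.0
_FRONT_BOOST = 0.8         # truth FRET ratio excess at a front tip
_FRONT_ZONE = 3.0          # um of front proximity carrying the boost


def _front_proximity(geometry: ChannelGeometry, mask: np.ndarray,
                     fronts: dict[str, float]) -> np.ndarray:
    """1 at a front tip decaying linearly to 0 over ``_FRONT_ZONE`` um."""
    label, s = geometry._regions()
    prox = np.zeros(geometry.image_shape)
    for code, side in ((2, "left"), (3, "right")):
        if side not in fronts:
            continue
        sel = mask & (label == code)
        gap = fronts[side] - s[sel]
        prox[sel] = np.maximum(prox[sel],
                               np.clip(1.0 - gap / _FRONT_ZONE, 0.0, 1.0))
    return prox


def _render_event(rng: np.random.Generator, params: GeneratorParams,
                  geometry: ChannelGeometry, event_id: str,
                  channels: tuple[str, ...],
                  stimulation: dict | None) -> tuple[EventMovie, EventLabel]:
    n_dec = _draw_duration_frames(rng, params) + 1
    ramp = _signal_ramp(n_dec, params.divergence_onset_fraction,
                        params.effect_size)
    onset = int(np.argmax(ramp > 0)) if np.any(ramp > 0) else n_dec - 1
    outcome = _draw_outcome(rng, params, stimulation, onset)
    win, lose = (("right", "left") if outcome == "right"
                 else ("left", "right"))

    max_ext = min(geometry.max_extension("left"),
                  geometry.max_extension("right")) - 1.0
    # relative front-speed modulation derived from the standardized effect
    mod = np.clip(0.3 * ramp, 0.0, 0.95)

    frames: list[FrameRecord] = []
    t = 0.0
    # approach
    tip = -_APPROACH_SPEED * _PRE_FRAMES
    rear = tip - _CELL_LENGTH
    states: list[dict] = []
    for _ in range(_PRE_FRAMES):
        states.append({"rear": rear, "tip": tip})
        tip += _APPROACH_SPEED
        rear += _APPROACH_SPEED
    # decision: contact at relative frame 0; frames 0..n_dec-2 protrude,
    # the first frame rendered after the loop shows the first retraction
    fl = fr = 0.0
    for k in range(n_dec - 1):
        fronts = {"left": min(fl, max_ext), "right": min(fr, max_ext)}
        states.append({"rear": rear, "fronts": dict(fronts)})
        gain = {win: _FRONT_SPEED * (1 + mod[k]),
                lose: _FRONT_SPEED * (1 - mod[k])}
        fl += gain["left"]
        fr += gain["right"]
        rear += _REAR_SPEED
    # resolution: losing front retracts
    for _ in range(_POST_FRAMES):
        gain = {win: _RETRACT_SPEED, lose: -_RETRACT_SPEED}
        fl += gain["left"]
        fr += gain["right"]
        rear += _RETRACT_SPEED
        fronts = {"left": min(fl, max_ext), "right": min(fr, max_ext)}
        if fronts[lose] <= 0.3:
            fronts.pop(lose)
        states.append({"rear": min(rear, -1.0), "fronts": fronts})

    for state in states:
        if "tip" in state:
            mask = geometry.rasterise_cell(state["rear"], state["tip"])
            fronts = {}
        else:
            f = state["fronts"]
            mask = geometry.rasterise_cell(state["rear"], 0.0,
                                           f.get("left"), f.get("right"))
            fronts = f
        chans: dict[str, np.ndarray] = {}
        prox = _front_proximity(geometry, mask, fronts)
        if "fret_donor" in channels or "fret_acceptor" in channels:
            truth = np.where(mask, 1.0 + _FRONT_BOOST * prox, 0.0)
            donor, acceptor = generate_fret_pair(
                truth, params, frame_index=len(frames), mask=mask, rng=rng)
            bg = rng.normal(_BACKGROUND, max(params.noise_sd, 1e-12),
                            mask.shape)
            chans["fret_donor"] = donor + bg
            chans["fret_acceptor"] = acceptor + bg
        if "actin" in channels:
            img = np.where(mask, _CYTO_LEVEL * (0.5 + prox), 0.0)
            img += rng.normal(_BACKGROUND, max(params.noise_sd, 1e-12),
                              mask.shape)
            chans["actin"] = np.clip(img, 0.0, None)
        if "myosin" in channels:
            label_img, s = geometry._regions()
            rearness = np.zeros(mask.shape)
            sel = mask & np.isfinite(s)
            rearness[sel] = np.clip(
                1.0 - (s[sel] - state["rear"]) / 4.0, 0.0, 1.0)
            img = np.where(mask, _CYTO_LEVEL * (0.3 + rearness), 0.0)
            img += rng.normal(_BACKGROUND, max(params.noise_sd, 1e-12),
                              mask.shape)
            chans["myosin"] = np.clip(img, 0.0, None)
        frames.append(FrameRecord(time=t, mask=mask, channels=chans))
        t += params.frame_interval

    movie = EventMovie(event_id=event_id, frames=frames, geometry=geometry,
                       frame_interval=params.frame_interval,
                       channel_names=channels)
    # ground truth landmarks: retraction_frame is the first frame whose
    # rendered mask shows retracted pixels of the losing front
    movie.contact_frame = _PRE_FRAMES
    movie.retraction_frame = _PRE_FRAMES + n_dec - 1
    movie.decision_duration = (n_dec - 1) * params.frame_interval
    label = EventLabel(outcome=outcome,
                       true_divergence_frame=_PRE_FRAMES + onset)
    return movie, label


# --------------------------------------------------------------------------
# Feature-tier event synthesis
# --------------------------------------------------------------------------

def _feature_event(rng: np.random.Generator, params: GeneratorParams,
                   event_id: str, informative: np.ndarray,
                   signs: np.ndarray,
                   stimulation: dict | None) -> tuple[FeatureTrajectory,
                                                      EventLabel]:
    n_frames = _draw_duration_frames(rng, params) + 1
    ramp = _signal_ramp(n_frames, params.divergence_onset_fraction,
                        params.effect_size)
    onset = int(np.argmax(ramp > 0)) if np.any(ramp > 0) else n_frames - 1
    outcome = _draw_outcome(rng, params, stimulation, onset)
    y_sign = 1.0 if outcome == "right" else -1.0

    values = rng.normal(0.0, params.noise_sd,
                        (n_frames, params.n_features))
    # class-conditional mean difference between outcomes equals the ramp
    values[:, informative] += (0.5 * y_sign * ramp[:, None]
                               * signs[None, :])
    times = np.arange(n_frames) * params.frame_interval
    traj = FeatureTrajectory(event_id=event_id, times=times, values=values)
    return traj, EventLabel(outcome=outcome, true_divergence_frame=onset)


# --------------------------------------------------------------------------
# Public generator
# --------------------------------------------------------------------------

def generate_dataset(params: GeneratorParams, tier: str = "feature",
                     geometry: ChannelGeometry | None = None,
                     channels: tuple[str, ...] = ("fret_donor",
                                                  "fret_acceptor"),
                     stimulation: dict | None = None) -> SyntheticDataset:
    """Generate ``params.n_events`` synthetic decision-making events.

    ``tier`` is ``"image"`` (full movies on ``geometry``) or ``"feature"``
    (per-frame feature vectors with the same statistical structure).  The
    informative feature subset (feature tier) is seed-chosen and recorded on
    the returned dataset.  Optional ``stimulation`` is a dict with keys
    ``side`` and ``pulse_frames``; with ``params.stimulation_bias > 0`` it
    tilts the outcome coin when a pulse lands at or after asymmetry onset.
    """
    if tier not in ("image", "feature"):
        raise ValueError("tier must be 'image' or 'feature'")
    rng = np.random.default_rng(params.seed)
    events: list[tuple[object, EventLabel]] = []

    if tier == "feature":
        informative = rng.choice(params.n_features,
                                 params.n_informative_features,
                                 replace=False)
        informative.sort()
        signs = rng.choice([-1.0, 1.0], params.n_informative_features)
        for i in range(params.n_events):
            events.append(_feature_event(rng, params, f"event{i:04d}",
                                         informative, signs, stimulation))
        return SyntheticDataset(events=events, params=params, tier=tier,
                                informative_features=informative,
                                feature_signs=signs)

    geometry = geometry or ChannelGeometry()
    h, w = geometry.image_shape
    for side in ("left", "right"):
        m = geometry.midline(side)
        if (m[:, 0].min() < 0 or m[:, 0].max() > h - 1
                or m[:, 1].min() < 0 or m[:, 1].max() > w - 1
                or geometry.max_extension(side) < 2.0):
            raise ValueError("branches do not fit the frame")
    for i in range(params.n_events):
        events.append(_render_event(rng, params, geometry, f"event{i:04d}",
                                    channels, stimulation))
    return SyntheticDataset(events=events, params=params, tier=tier)


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_image_event(movie: EventMovie, label: EventLabel,
                      outdir: str | Path) -> None:
    """Write one event as per-channel multi-page TIFFs + a JSON sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{movie.event_id}_mask.tif",
                     movie.masks().astype(np.uint8))
    for name in movie.channel_names:
        tifffile.imwrite(outdir / f"{movie.event_id}_{name}.tif",
                         movie.channel_stack(name).astype(np.float32))
    sidecar = {
        "event_id": movie.event_id,
        "frame_interval": movie.frame_interval,
        "channel_names": list(movie.channel_names),
        "outcome": label.outcome,
        "true_divergence_frame": label.true_divergence_frame,
        "contact_frame": getattr(movie, "contact_frame", None),
        "retraction_frame": getattr(movie, "retraction_frame", None),
        "geometry": movie.geometry.to_dict(),
    }
    (outdir / f"{movie.event_id}.json").write_text(
        json.dumps(sidecar, indent=1))


def write_feature_dataset(dataset: SyntheticDataset,
                          path: str | Path,
                          feature_names: list[str] | None = None
                          ) -> pd.DataFrame:
    """Write a feature-tier dataset as a long-format CSV table."""
    if dataset.tier != "feature":
        raise ValueError("expected a feature-tier dataset")
    n_feat = dataset.params.n_features
    if feature_names is None:
        feature_names = [f"f{j:04d}" for j in range(n_feat)]
    rows = []
    for traj, lab in dataset.events:
        f_idx, frame_idx = np.meshgrid(np.arange(n_feat),
                                       np.arange(len(traj.times)))
        rows.append(pd.DataFrame({
            "event_id": traj.event_id,
            "frame": frame_idx.ravel(),
            "feature_name": np.asarray(feature_names)[f_idx.ravel()],
            "value": traj.values.ravel(),
            "label": 1 if lab.outcome == "right" else 0,
        }))
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(path, index=False)
    return table
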