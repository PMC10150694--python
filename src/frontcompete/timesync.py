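"""Time synchronisation of decision-making events.

Cells resolve their two competing fronts at different rates, so per-frame
feature trajectories are not directly comparable across events.  This module
(1) keeps only events whose decision duration (contact with the obstacle to
retraction initiation) lies within one standard deviation of the population
mean, and (2) maps each kept event onto a common rescaled time in [0, 1],
resampling every feature trajectory at ``n_points`` equally spaced timepoints
with a cubic smoothing spline.

The smoothing parameter ``p`` follows the convention where 0 fits a straight
line and 1 gives a total (interpolating) fit; the spline minimises

    p * sum_i (y_i - f(x_i))^2  +  (1 - p) * integral f''(t)^2 dt

over natural cubic splines, solved in closed form (Green & Silverman).  All
columns of an event share the knot vector, so one factorisation interpolates
the full feature bank at once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyncConfig",
    "SyncFeatureTensor",
    "duration_window",
    "filter_by_duration",
    "smoothing_spline",
    "interpolate_event",
    "sync_dataset",
    "write_tensor",
]


@dataclass
class SyncConfig:
    n_points: int = 15
    smooth_p: float = 0.5

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0.0 <= self.smooth_p <= 1.0:
            raise ValueError("smooth_p must be in [0, 1]")


@dataclass
class SyncFeatureTensor:
    """Events x interpolated-timepoints x features, with outcome labels."""

    values: np.ndarray            # (n_events, n_points, n_features)
    labels: np.ndarray            # (n_events,) right = 1, left = 0
    grid: np.ndarray              # (n_points,) rescaled time in [0, 1]
    kept: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per kept event required")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def timepoint_matrix(self, t: int) -> np.ndarray:
        """Events x features design matrix at interpolated timepoint ``t``."""
        return self.values[:, t, :]


# --------------------------------------------------------------------------
# Duration filter
# --------------------------------------------------------------------------

def duration_window(mean: float, sd: float) -> tuple[float, float]:
    """Inclusive one-standard-deviation acceptance window around the mean.

    With the population values 45 s +/- 15 s this is [30, 60] s.
    """
    return mean - sd, mean + sd


def filter_by_duration(durations) -> tuple[np.ndarray, np.ndarray,
                                           tuple[float, float]]:
    """Keep events whose duration is within 1 SD of the population mean.

    The mean and standard deviation are computed on the input population.
    Returns (kept indices, dropped indices, window); bounds are inclusive.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 events to define a population")
    lo, hi = duration_window(durations.mean(), durations.std(ddof=1))
    keep = (durations >= lo) & (durations <= hi)
    idx = np.arange(durations.size)
    return idx[keep], idx[~keep], (lo, hi)


# --------------------------------------------------------------------------
# Cubic smoothing spline (natural boundary conditions)
# --------------------------------------------------------------------------

def _spline_matrices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Banded Q (n x n-2) and R (n-2 x n-2) of the roughness penalty."""
    n = x.size
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q, R


def smoothing_spline(x: np.ndarray, y: np.ndarray, p: float):
    """Fit natural cubic smoothing splines to the columns of ``y``.

    ``x`` is strictly increasing, shape (n,); ``y`` is (n,) or (n, m).
    Returns a callable evaluating the fitted spline(s) at query points.
    ``p = 0`` returns the least-squares line, ``p = 1`` the natural cubic
    interpolant; in between the roughness penalty weight is (1 - p) / p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trajectory")
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    n = x.size

    if p == 0.0:
        design = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)

        def line(t):
            t = np.asarray(t, dtype=float)
            out = beta[0] + np.outer(t, beta[1])
            return out[:, 0] if squeeze else out
        return line

    Q, R = _spline_matrices(x)
    alpha = (1.0 - p) / p
    K = Q @ np.linalg.solve(R, Q.T)
    fhat = np.linalg.solve(np.eye(n) + alpha * K, Y)
    gamma_int = np.linalg.solve(R, Q.T @ fhat)
    gamma = np.zeros_like(fhat)
    gamma[1:-1] = gamma_int          # natural: zero curvature at the ends

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(x, t, side="right") - 1, 0, n - 2)
        h = x[i + 1] - x[i]
        a = (x[i + 1] - t) / h
        b = (t - x[i]) / h
        c = (t - x[i]) * (x[i + 1] - t) / 6.0
        out = (a[:, None] * fhat[i] + b[:, None] * fhat[i + 1]
               - c[:, None] * ((1.0 + a)[:, None] * gamma[i]
                               + (1.0 + b)[:, None] * gamma[i + 1]))
        return out[:, 0] if squeeze else out
    return evaluate


def interpolate_event(times: np.ndarray, values: np.ndarray,
                      config: SyncConfig | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Resample one event's feature trajectories onto the rescaled grid.

    ``times`` (n,) are frame times (contact to retraction initiation) and
    ``values`` is (n,) or (n, n_features).  The trajectory is rescaled to
    [0, 1] and the smoothing spline evaluated at ``config.n_points`` equally
    spaced points including both endpoints.  Traces shorter than 4 frames use
    a linear fallback (with a warning).  Returns (grid, interpolated values).
    """
    config = config or SyncConfig()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.shape[0]:
        raise ValueError("times and values length mismatch")
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("event must span a positive duration")
    u = (times - times[0]) / span
    grid = np.linspace(0.0, 1.0, config.n_points)
    if times.size < 4:
        warnings.warn("fewer than 4 frames: linear interpolation fallback",
                      stacklevel=2)
        if values.ndim == 1:
            out = np.interp(grid, u, values)
        else:
            out = np.column_stack([np.interp(grid, u, col)
                                   for col in values.T])
        return grid, out
    spline = smoothing_spline(u, values, config.smooth_p)
    out = spline(grid)
    if not np.all(np.isfinite(out)):
        raise ValueError("interpolation produced non-finite output")
    return grid, out


# --------------------------------------------------------------------------
# Dataset-level synchronisation
# --------------------------------------------------------------------------

def sync_dataset(trajectories, labels, config: SyncConfig | None = None,
                 feature_names: list[str] | None = None) -> SyncFeatureTensor:
    """Filter by duration and interpolate a collection of events.

    ``trajectories`` is a sequence of objects with ``times`` (n_i,),
    ``values`` (n_i, n_features) and ``event_id``; ``labels`` the matching
    binary outcomes (right = 1, left = 0).
    """
    config = config or SyncConfig()
    labels = np.asarray(labels)
    durations = np.array([t.times[-1] - t.times[0] for t in trajectories])
    kept_idx, dropped_idx, _ = filter_by_duration(durations)
    stacks = []
    for i in kept_idx:
        traj = trajectories[i]
        grid, vals = interpolate_event(traj.times, traj.values, config)
        stacks.append(vals)
    if not stacks:
        raise ValueError("duration filter kept no events")
    values = np.stack(stacks)
    n_feat = values.shape[2]
    if feature_names is None:
        feature_names = [f"f{j:04d}" for j in range(n_feat)]
    return SyncFeatureTensor(
        values=values,
        labels=labels[kept_idx],
        grid=np.linspace(0.0, 1.0, config.n_points),
        kept=[trajectories[i].event_id for i in kept_idx],
        dropped=[trajectories[i].event_id for i in dropped_idx],
        feature_names=list(feature_names),
    )


def write_tensor(tensor: SyncFeatureTensor, csv_path: str | Path,
                 manifest_path: str | Path | None = None) -> None:
    """Write the tensor as a wide CSV plus a JSON kept/dropped manifest."""
    n_e, n_t, n_f = tensor.values.shape
    cols = {"event_id": tensor.kept, "label": tensor.labels}
    flat = tensor.values.reshape(n_e, n_t * n_f)
    names = [f"t{t:02d}_{tensor.feature_names[j]}"
             for t in range(n_t) for j in range(n_f)]
    frame = pd.DataFrame(flat, columns=names)
    for k, v in reversed(cols.items()):
        frame.insert(0, k, v)
    frame.to_csv(csv_path, index=False)
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps({
            "kept": list(tensor.kept),
            "dropped": list(tensor.dropped),
            "n_points": n_t,
            "n_features": n_f,
        }, indent=1))
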