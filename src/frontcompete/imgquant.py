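"""Image quantification for bifurcation decision-making movies.

Implements the measurement stack applied to each event movie: cell
segmentation with local background subtraction and edge enhancement,
ratiometric FRET activity with flat-field ("ratio correction") and
photobleaching corrections, branch-front regions (the 400 cell pixels
nearest the front edge), protrusion/retraction speeds from front-region
masks, skeleton-based cell length and area, and the event landmarks
(contact, retraction initiation, big retraction) that define the
decision-making interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.filters import gaussian as _gaussian, threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import resize as _resize

from .synthgen import ChannelGeometry, EventMovie

__all__ = [
    "CorrectionImages",
    "FrontTrace",
    "KineticsTrace",
    "EventAnnotation",
    "segment",
    "ratio_correction_image",
    "fret_ratio",
    "front_region",
    "front_activity",
    "edge_speeds",
    "kinetics",
    "annotate_event",
    "quantify_event",
]

_SIDE_CODE = {"left": 2, "right": 3}


@dataclass
class CorrectionImages:
    ratio_correction: np.ndarray
    bleach_slope: float = 0.0        # signed rate of b(t) = 1 + slope * t
    block_size: int = 24
    smooth_sigma: float = 5.0

    def __post_init__(self) -> None:
        if np.any(self.ratio_correction <= 0):
            raise ValueError("ratio correction must be strictly positive")


@dataclass
class FrontTrace:
    """Per-frame, per-side front measurements for one event."""

    event_id: str
    times: np.ndarray
    edge_points: dict              # side -> (T, 2) float, NaN when absent
    extensions: dict               # side -> (T,) um past apex
    activity: dict                 # side -> (T,) corrected sumA/sumD
    region_sizes: dict             # side -> (T,) int
    protrusion_speed: dict         # side -> (T,) um^2/min (NaN at tail)
    retraction_speed: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for side in ("left", "right"):
            for t in range(len(self.times)):
                rows.append({
                    "event_id": self.event_id, "frame": t, "side": side,
                    "time": self.times[t],
                    "edge_row": self.edge_points[side][t][0],
                    "edge_col": self.edge_points[side][t][1],
                    "extension_um": self.extensions[side][t],
                    "activity": self.activity[side][t],
                    "region_size": self.region_sizes[side][t],
                    "protrusion_um2_min": self.protrusion_speed[side][t],
                    "retraction_um2_min": self.retraction_speed[side][t],
                })
        return pd.DataFrame(rows)


@dataclass
class KineticsTrace:
    """Skeleton length and mask area per frame, absolute and relative."""

    length_um: np.ndarray
    area_um2: np.ndarray
    rel_length: np.ndarray
    rel_area: np.ndarray
    reference_frame: int

    def to_dataframe(self, event_id: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "event_id": event_id,
            "frame": np.arange(self.length_um.size),
            "length_um": self.length_um, "area_um2": self.area_um2,
            "rel_length": self.rel_length, "rel_area": self.rel_area,
        })


@dataclass
class EventAnnotation:
    contact_frame: int
    retraction_init_frame: int
    big_retraction_frame: int | None
    outcome: str
    duration: float                # s, contact -> retraction initiation
    retracting_side: str = ""
    cumulative_retraction_um2: np.ndarray = field(
        default_factory=lambda: np.array([]))


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def _local_background(image: np.ndarray, bg_mask: np.ndarray,
                      window: int = 51, stride: int = 16) -> np.ndarray:
    """Median of conservatively-background pixels in a local window,
    evaluated on a coarse grid and bilinearly interpolated."""
    h, w = image.shape
    half = window // 2
    grid_r = np.arange(half, h, stride)
    grid_c = np.arange(half, w, stride)
    if grid_r[-1] < h - 1:
        grid_r = np.append(grid_r, h - 1)
    if grid_c[-1] < w - 1:
        grid_c = np.append(grid_c, w - 1)
    vals = np.full((grid_r.size, grid_c.size), np.nan)
    for i, r in enumerate(grid_r):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        for j, c in enumerate(grid_c):
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            patch = image[r0:r1, c0:c1][bg_mask[r0:r1, c0:c1]]
            if patch.size:
                vals[i, j] = np.median(patch)
    if np.isnan(vals).any():
        nan = np.isnan(vals)
        if nan.all():
            raise ValueError("no background pixels found")
        idx = ndimage.distance_transform_edt(nan, return_indices=True)[1]
        vals = vals[tuple(idx)]
    interp = RegularGridInterpolator((grid_r, grid_c), vals,
                                     bounds_error=False, fill_value=None)
    rr, cc = np.mgrid[0:h, 0:w]
    return interp(np.column_stack([rr.ravel(), cc.ravel()])
                  ).reshape(h, w)


def segment(image: np.ndarray, smooth_sigma: float = 5.0,
            background_window: int = 51) -> np.ndarray:
    """Binary cell mask from a single non-negative channel.

    For FRET data pass the sum of the aligned donor and acceptor images.
    Background is estimated as the median of conservatively-background
    pixels (below the raw Otsu cut) in the local neighbourhood and
    subtracted; edges are enhanced by subtracting a gaussian-smoothed
    (sigma = 5) copy; Otsu thresholding of the result and retention of the
    largest 8-connected component give the mask.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if img.max() == img.min():
        raise ValueError("constant image: no foreground/background split")
    bg_mask = img < threshold_otsu(img)
    background = _local_background(img, bg_mask, background_window)
    sub = img - background
    enhanced = sub - _gaussian(sub, sigma=smooth_sigma,
                               preserve_range=True)
    thr = threshold_otsu(enhanced)
    raw = enhanced > thr
    lab, n = ndimage.label(raw, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("no object found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# --------------------------------------------------------------------------
# FRET corrections and ratio
# --------------------------------------------------------------------------

def ratio_correction_image(ratio_stack: np.ndarray, masks: np.ndarray,
                           block_size: int = 24,
                           smooth_sigma: float = 5.0) -> np.ndarray:
    """Flat-field correction for the systematic spatial gradient in the
    apparent FRET ratio.

    Per-pixel median of the ratio over the stack (cell pixels only), reduced
    to ``block_size`` x ``block_size`` block medians, upsampled to the input
    shape and gaussian-smoothed (sigma in pixels).  Blocks containing no
    cell pixel anywhere in the stack are filled from the nearest valid block
    (with a warning).  The result is strictly positive.
    """
    stack = np.asarray(ratio_stack, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    if stack.shape != masks.shape:
        raise ValueError("stack/mask shape mismatch")
    data = np.where(masks, stack, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(data, axis=0)
    h, w = med.shape
    nb_r = int(np.ceil(h / block_size))
    nb_c = int(np.ceil(w / block_size))
    blocks = np.full((nb_r, nb_c), np.nan)
    for i in range(nb_r):
        for j in range(nb_c):
            patch = med[i * block_size:(i + 1) * block_size,
                        j * block_size:(j + 1) * block_size]
            good = np.isfinite(patch)
            if good.any():
                blocks[i, j] = np.median(patch[good])
    nan = np.isnan(blocks)
    if nan.any():
        if nan.all():
            raise ValueError("no cell pixels anywhere in the stack")
        warnings.warn(f"{int(nan.sum())} blocks without cell pixels filled "
                      "from nearest neighbours", stacklevel=2)
        idx = ndimage.distance_transform_edt(nan, return_indices=True)[1]
        blocks = blocks[tuple(idx)]
    full = _resize(blocks, (h, w), order=1, mode="edge",
                   anti_aliasing=False)
    full = _gaussian(full, sigma=smooth_sigma, mode="nearest",
                     preserve_range=True)
    return np.clip(full, 1e-9, None)


def fret_ratio(donor: np.ndarray, acceptor: np.ndarray, mask: np.ndarray,
               correction: np.ndarray | None = None) -> np.ndarray:
    """Acceptor/donor ratio inside the mask, flat-field corrected.

    Pixels outside the mask are NaN ("defined as not a number"); donor
    pixels <= 0 inside the mask are marked NaN with a warning.  Backgrounds
    are assumed already subtracted.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape or donor.shape != mask.shape:
        raise ValueError("shape mismatch")
    ratio = np.full(donor.shape, np.nan)
    ok = mask & (donor > 0)
    bad = mask & ~(donor > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} in-mask pixels with non-positive "
                      "donor marked missing", stacklevel=2)
    ratio[ok] = acceptor[ok] / donor[ok]
    if correction is not None:
        ratio = ratio / correction
    return ratio


# --------------------------------------------------------------------------
# Front regions and activity
# --------------------------------------------------------------------------

def front_region(mask: np.ndarray, geometry: ChannelGeometry, side: str,
                 n_pixels: int = 400
                 ) -> tuple[tuple[int, int], np.ndarray]:
    """Front edge point and the front region for one branch.

    The edge point is the farthest-along-branch intersection of the branch
    midline with the cell mask; the region holds the ``n_pixels`` in-branch
    cell pixels closest (Euclidean, centre-to-centre; ties broken row-major)
    to the edge point.  If the branch holds fewer pixels, all are returned
    with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    label, _ = geometry._regions()
    code = _SIDE_CODE[side]
    midline = geometry.midline(side)
    mr = np.clip(np.round(midline[:, 0]).astype(int), 0,
                 mask.shape[0] - 1)
    mc = np.clip(np.round(midline[:, 1]).astype(int), 0,
                 mask.shape[1] - 1)
    on = mask[mr, mc]
    if not on.any():
        raise ValueError(f"mask absent from {side} branch midline")
    k = int(np.flatnonzero(on)[-1])          # farthest along the branch
    edge = (int(mr[k]), int(mc[k]))
    rows, cols = np.nonzero(mask & (label == code))
    if rows.size == 0:
        raise ValueError(f"mask absent from {side} branch")
    dist = np.hypot(rows - edge[0], cols - edge[1])
    order = np.lexsort((cols, rows, dist))
    if rows.size < n_pixels:
        warnings.warn(f"only {rows.size} in-branch pixels available "
                      f"(< {n_pixels})", stacklevel=2)
    take = order[:min(n_pixels, rows.size)]
    region = np.column_stack([rows[take], cols[take]])
    return edge, region


def front_activity(donor: np.ndarray, acceptor: np.ndarray,
                   region: np.ndarray, bleach_slope: float = 0.0,
                   frame_index: int = 0) -> float:
    """Front FRET activity: sum of acceptor over sum of donor in the region,
    photobleaching-corrected.

    The correction divides by the linear multiplicative bleach model
    b(t) = 1 + bleach_slope * frame_index, where ``bleach_slope`` is the
    signed fitted rate (negative for signal loss).
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty front region")
    rr, cc = region[:, 0], region[:, 1]
    sd = float(np.nansum(donor[rr, cc]))
    sa = float(np.nansum(acceptor[rr, cc]))
    if sd <= 0:
        raise ValueError("non-positive donor sum: activity undefined")
    return (sa / sd) / (1.0 + bleach_slope * frame_index)


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

def edge_speeds(mask_t: np.ndarray, mask_t2: np.ndarray, dt: float,
                pixel_size: float = 0.21) -> tuple[float, float]:
    """Protrusion and retraction speeds (um^2/min) between two masks.

    Masks are compared every other frame (dt = 2 x frame interval):
    protrusion counts newly occupied pixels, retraction newly vacated ones;
    each area is divided by dt in minutes.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(mask_t, dtype=bool)
    b = np.asarray(mask_t2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    px2 = pixel_size ** 2
    minutes = dt / 60.0
    protrusion = int(np.count_nonzero(b & ~a)) * px2 / minutes
    retraction = int(np.count_nonzero(a & ~b)) * px2 / minutes
    return protrusion, retraction


def _skeleton_length(mask: np.ndarray, pixel_size: float) -> float:
    """Length of the morphological skeleton: orthogonal steps count 1 pixel,
    diagonal steps sqrt(2) (8-connected, diagonals only where no orthogonal
    link already joins the pixels)."""
    sk = skeletonize(mask)
    n_orth = (np.count_nonzero(sk[:, :-1] & sk[:, 1:])
              + np.count_nonzero(sk[:-1, :] & sk[1:, :]))
    # a diagonal pair already linked through an orthogonal neighbour is a
    # triangle artefact of 8-connectivity; count only true diagonal steps
    d1 = sk[:-1, :-1] & sk[1:, 1:] & ~(sk[:-1, 1:] | sk[1:, :-1])
    d2 = sk[:-1, 1:] & sk[1:, :-1] & ~(sk[:-1, :-1] | sk[1:, 1:])
    n_diag = int(np.count_nonzero(d1) + np.count_nonzero(d2))
    return (n_orth + np.sqrt(2.0) * n_diag) * pixel_size


def kinetics(masks: np.ndarray, reference_frame: int = 0,
             pixel_size: float = 0.21) -> KineticsTrace:
    """Cell length (skeleton) and area per frame, plus values relative to a
    reference frame (the contact frame, or the fronts-separated frame,
    depending on the analysis — the caller chooses)."""
    masks = np.asarray(masks, dtype=bool)
    lengths, areas = [], []
    for m in masks:
        n = int(np.count_nonzero(m))
        if n == 0:
            raise ValueError("empty mask")
        lengths.append(_skeleton_length(m, pixel_size))
        areas.append(n * pixel_size ** 2)
    length = np.asarray(lengths)
    area = np.asarray(areas)
    if not 0 <= reference_frame < len(masks):
        raise ValueError("reference_frame out of range")
    return KineticsTrace(length_um=length, area_um2=area,
                         rel_length=length / length[reference_frame],
                         rel_area=area / area[reference_frame],
                         reference_frame=reference_frame)


# --------------------------------------------------------------------------
# Event landmarks
# --------------------------------------------------------------------------

def _branch_masks(mask: np.ndarray, geometry: ChannelGeometry) -> dict:
    label, _ = geometry._regions()
    return {side: mask & (label == code)
            for side, code in _SIDE_CODE.items()}


def annotate_event(movie: EventMovie,
                   geometry: ChannelGeometry | None = None,
                   big_retraction_threshold: float = 7.2
                   ) -> EventAnnotation:
    """Contact, retraction-initiation and big-retraction landmarks.

    Contact is the first frame whose mask touches the obstacle boundary.
    Retraction initiation is the first frame with a positive retracted area
    of one branch front (frame-to-frame vacated pixels); the projected
    retraction area is accumulated from there, and the big retraction fires
    at the first frame where it exceeds ``big_retraction_threshold`` (um^2,
    default 7.2).  The outcome is the side opposite the retracting front.
    """
    geometry = geometry or movie.geometry
    px2 = geometry.pixel_size ** 2
    masks = movie.masks()
    obstacle = geometry.obstacle_mask()
    ring = ndimage.binary_dilation(obstacle, np.ones((3, 3))) & ~obstacle
    touching = [bool((m & ring).any()) for m in masks]
    if not any(touching):
        raise ValueError("cell never contacts the obstacle")
    contact = int(np.argmax(touching))

    branch = [_branch_masks(m, geometry) for m in masks]
    retraction_init = None
    losing = None
    for t in range(contact + 1, len(masks)):
        ret = {s: int(np.count_nonzero(branch[t - 1][s] & ~branch[t][s]))
               for s in ("left", "right")}
        shrinking = [s for s in ("left", "right") if ret[s] > 0]
        if len(shrinking) == 2:
            raise ValueError(
                f"both fronts retract first at frame {t}: tie")
        if len(shrinking) == 1:
            retraction_init, losing = t, shrinking[0]
            break
    if retraction_init is None:
        raise ValueError("no front retraction found")

    cum = []
    total = 0.0
    big = None
    for t in range(retraction_init, len(masks)):
        prev = branch[t - 1][losing]
        total += int(np.count_nonzero(prev & ~branch[t][losing])) * px2
        cum.append(total)
        if big is None and total > big_retraction_threshold:
            big = t
    outcome = "right" if losing == "left" else "left"
    return EventAnnotation(
        contact_frame=contact, retraction_init_frame=retraction_init,
        big_retraction_frame=big, outcome=outcome,
        duration=(retraction_init - contact) * movie.frame_interval,
        retracting_side=losing,
        cumulative_retraction_um2=np.asarray(cum))


# --------------------------------------------------------------------------
# Whole-event quantification
# --------------------------------------------------------------------------

def quantify_event(movie: EventMovie,
                   geometry: ChannelGeometry | None = None,
                   correction: CorrectionImages | None = None,
                   n_region_pixels: int = 400) -> FrontTrace:
    """Per-frame, per-side front measurements for one movie.

    Computes front edge points, extensions past the apex, front regions,
    bleach-corrected FRET activity (when donor/acceptor channels exist) and
    front protrusion/retraction speeds (region masks compared every other
    frame)."""
    geometry = geometry or movie.geometry
    T = len(movie.frames)
    times = np.array([f.time for f in movie.frames])
    arc = {s: geometry.midline_arclength(s) for s in ("left", "right")}
    midline_px = {}
    for s in ("left", "right"):
        m = geometry.midline(s)
        midline_px[s] = (np.clip(np.round(m[:, 0]).astype(int), 0,
                                 geometry.image_shape[0] - 1),
                         np.clip(np.round(m[:, 1]).astype(int), 0,
                                 geometry.image_shape[1] - 1))
    bleach = correction.bleach_slope if correction else 0.0
    corr_img = correction.ratio_correction if correction else None
    has_fret = ("fret_donor" in movie.channel_names
                and "fret_acceptor" in movie.channel_names)

    out = {k: {s: np.full(T, np.nan) for s in ("left", "right")}
           for k in ("ext", "act", "prot", "ret")}
    edge_pts = {s: np.full((T, 2), np.nan) for s in ("left", "right")}
    sizes = {s: np.zeros(T, dtype=int) for s in ("left", "right")}
    region_masks = {s: [None] * T for s in ("left", "right")}

    label_img, _ = geometry._regions()
    for t, frame in enumerate(movie.frames):
        for s in ("left", "right"):
            mr, mc = midline_px[s]
            if not frame.mask[mr, mc].any():
                continue
            if not (frame.mask & (label_img == _SIDE_CODE[s])).any():
                continue           # midline touched in the stem only
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                edge, region = front_region(frame.mask, geometry, s,
                                            n_region_pixels)
            edge_pts[s][t] = edge
            k = int(np.flatnonzero(frame.mask[mr, mc])[-1])
            out["ext"][s][t] = arc[s][k]
            sizes[s][t] = len(region)
            rm = np.zeros(geometry.image_shape, dtype=bool)
            rm[region[:, 0], region[:, 1]] = True
            region_masks[s][t] = rm
            if has_fret:
                donor = frame.channels["fret_donor"]
                acceptor = frame.channels["fret_acceptor"]
                if corr_img is not None:
                    ratio = fret_ratio(donor, acceptor, frame.mask,
                                       corr_img)
                    sel = region[:, 0], region[:, 1]
                    vals = ratio[sel]
                    good = np.isfinite(vals)
                    d = donor[sel][good]
                    out["act"][s][t] = (float(np.sum(vals[good] * d))
                                        / float(np.sum(d))
                                        / (1.0 + bleach * t)) \
                        if d.size else np.nan
                else:
                    out["act"][s][t] = front_activity(
                        donor, acceptor, region, bleach, t)

    for s in ("left", "right"):
        for t in range(T - 2):
            a, b = region_masks[s][t], region_masks[s][t + 2]
            if a is None or b is None:
                continue
            p, r = edge_speeds(a, b, 2 * movie.frame_interval,
                               geometry.pixel_size)
            out["prot"][s][t] = p
            out["ret"][s][t] = r

    return FrontTrace(event_id=movie.event_id, times=times,
                      edge_points=edge_pts, extensions=out["ext"],
                      activity=out["act"], region_sizes=sizes,
                      protrusion_speed=out["prot"],
                      retraction_speed=out["ret"])
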