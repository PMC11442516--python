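"""Vessel-center detection and plausibility tracking.

Two detectors propose vessel-center candidates per frame:

* **Template matching** — the operator cuts a template of the vessel
  cross-section at the scan start; each new B-mode frame is scored with the
  (non-centered) normalized correlation coefficient

      C_all(x, y) = sum T·I / sqrt(sum T^2 · sum I^2)

  over all placements, and the highest local maxima become the ranked
  candidates ``C_v`` (candidate position = template *center*).

* **Doppler color extraction** — the Doppler cross-section is converted to
  HSV; pixels inside the red-flow ranges (hue in [0,10] or [170,180],
  saturation in [50,255], value in [20,255], OpenCV-style scales) are
  segmented into 8-connected components, sorted by area, and greedily merged
  into clusters whenever a centroid lies within ``T_cl`` (default 50 px,
  roughly the artery radius) of the current cluster centroid, recomputing the
  area-weighted centroid after every absorption.  Cluster centroids become
  the ranked candidates.

A plausibility step then updates the persisted vessel center P^t: the
candidate nearest the previous center is accepted only if it moved at most
``T_d`` (default 50 px); otherwise — and when no candidate exists at all —
the previous center is retained.  This gate is what keeps a single bad frame
from steering the probe away from the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .phantom import BModeFrame, DopplerXPlaneFrame

__all__ = [
    "Template",
    "CorrelationMap",
    "HsvRanges",
    "RedRegion",
    "VesselCandidate",
    "TrackerState",
    "TrackingParams",
    "TrackerNotInitializedError",
    "match_template",
    "rank_template_candidates",
    "hsv_in_red_range",
    "extract_red_regions",
    "merge_clusters",
    "update_vessel_position",
    "track_frame",
]


class TrackerNotInitializedError(RuntimeError):
    """The tracker has no seed position; the operator must select one."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class Template:
    """Grayscale template patch T(x', y') cut at the scan start."""

    pixels: np.ndarray
    origin_px: Tuple[int, int] = (0, 0)
    source_frame_index: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("template must be a non-empty 2D patch")
        if not np.any(p):
            raise ValueError("template must not be all-zero")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class CorrelationMap:
    """NCC similarity C_all(x, y) for every valid template placement."""

    values: np.ndarray  # (H - th + 1, W - tw + 1)
    template_shape: Tuple[int, int]
    offset_px: Tuple[int, int] = (0, 0)  # search-window origin in the image


@dataclass(frozen=True)
class HsvRanges:
    """Red-flow HSV gates on OpenCV-style scales (H: [0,180]; S, V: [0,255])."""

    hue_low: Tuple[float, float] = (0.0, 10.0)
    hue_high: Tuple[float, float] = (170.0, 180.0)
    saturation: Tuple[float, float] = (50.0, 255.0)
    value: Tuple[float, float] = (20.0, 255.0)

    def __post_init__(self) -> None:
        for lo, hi, top in (
            (*self.hue_low, 180.0),
            (*self.hue_high, 180.0),
            (*self.saturation, 255.0),
            (*self.value, 255.0),
        ):
            if not (0.0 <= lo <= hi <= top):
                raise ValueError("HSV intervals must lie within channel bounds")


DEFAULT_HSV_RANGES = HsvRanges()


@dataclass
class RedRegion:
    """A connected component of red flow pixels."""

    centroid_px: Tuple[float, float]  # (x, y)
    area_px: int
    bbox: Tuple[int, int, int, int] = (0, 0, 0, 0)  # (min_row, min_col, max_row, max_col)

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("region area must be positive")


@dataclass
class VesselCandidate:
    position_px: Tuple[float, float]
    score: float
    rank: int = 0


@dataclass
class TrackerState:
    """Persisted vessel center P^t plus the per-frame decision history."""

    position_px: Optional[Tuple[float, float]] = None
    last_update_frame: int = -1
    history: List[tuple] = field(default_factory=list)  # (frame, position, accepted)

    @classmethod
    def seeded(cls, position_px, frame_index: int = 0) -> "TrackerState":
        """Operator-selected initial vessel position P^0."""
        pos = (float(position_px[0]), float(position_px[1]))
        return cls(position_px=pos, last_update_frame=frame_index, history=[(frame_index, pos, True)])


@dataclass
class TrackingParams:
    """Gating thresholds: T_cl (cluster merge) and T_d (frame-to-frame)."""

    T_cl_px: float = 50.0
    T_d_px: float = 50.0
    n_candidates: int = 5
    min_region_area_px: int = 5  # suppress single-pixel color noise

    def __post_init__(self) -> None:
        if min(self.T_cl_px, self.T_d_px) <= 0 or self.n_candidates <= 0:
            raise ValueError("tracking parameters must be positive")


# ---------------------------------------------------------------------------
# template matching
# ---------------------------------------------------------------------------
def match_template(image, template) -> CorrelationMap:
    """Normalized correlation coefficient of the template at every placement.

    ``image`` may be a :class:`~sonoservo.phantom.BModeFrame` or a 2D array;
    ``template`` a :class:`Template` or a 2D array.  For nonnegative images
    every value is bounded by 1 (Cauchy–Schwarz), with equality exactly when
    the image patch is proportional to the template.  Placements where the
    image patch has zero energy score 0 by convention.

    Small inputs are correlated directly (exact for integer-valued pixels);
    large ones via FFT.
    """
    img = image.pixels if isinstance(image, BModeFrame) else np.asarray(image)
    img = np.asarray(img, dtype=float)
    tpl = template.pixels if isinstance(template, Template) else np.asarray(template, dtype=float)
    if img.ndim != 2 or tpl.ndim != 2:
        raise ValueError("image and template must be 2D grayscale arrays")
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise ValueError(f"template {tpl.shape} larger than image {img.shape}")
    t_energy = float(np.sum(tpl * tpl))
    if t_energy == 0.0:
        raise ValueError("template has zero energy")

    method = "direct" if img.size <= 64 * 64 else "fft"
    num = signal.correlate(img, tpl, mode="valid", method=method)
    patch_energy = signal.correlate(img * img, np.ones_like(tpl), mode="valid", method=method)
    patch_energy = np.maximum(patch_energy, 0.0)  # FFT roundoff guard
    denom = np.sqrt(t_energy * patch_energy)
    eps = 1e-12 * max(t_energy, 1.0)
    values = np.where(denom > eps, num / np.where(denom > eps, denom, 1.0), 0.0)
    return CorrelationMap(values=values, template_shape=tpl.shape)


def rank_template_candidates(
    corr_map: CorrelationMap, n: int, min_separation_px: float | None = None
) -> List[VesselCandidate]:
    """Top-n local correlation maxima as ranked candidates.

    A placement qualifies when its score is positive and not exceeded in its
    8-neighbourhood; equal-score ties are broken in row-major (y, then x)
    scan order.  Nearby maxima within ``min_separation_px`` (default: a
    quarter of the smaller template side, at least 3 px) of a better one are
    suppressed.  Candidate positions are template-*center* pixels.
    """
    vals = corr_map.values
    if vals.size == 0:
        return []
    if min_separation_px is None:
        min_separation_px = max(3.0, min(corr_map.template_shape) / 4.0)
    footprint_max = ndimage.maximum_filter(vals, size=3, mode="constant", cval=-np.inf)
    peak_mask = (vals >= footprint_max) & (vals > 0.0)
    ys, xs = np.nonzero(peak_mask)
    if len(ys) == 0:
        return []
    scores = vals[ys, xs]
    order = np.lexsort((xs, ys, -scores))  # score desc, then row-major
    th, tw = corr_map.template_shape
    oy, ox = corr_map.offset_px[1], corr_map.offset_px[0]
    chosen: List[VesselCandidate] = []
    kept_xy: List[Tuple[float, float]] = []
    for idx in order:
        y, x = float(ys[idx]), float(xs[idx])
        if any((y - ky) ** 2 + (x - kx) ** 2 < min_separation_px**2 for ky, kx in kept_xy):
            continue
        kept_xy.append((y, x))
        pos = (x + tw // 2 + ox, y + th // 2 + oy)
        chosen.append(VesselCandidate(position_px=pos, score=float(scores[idx]), rank=len(chosen) + 1))
        if len(chosen) >= n:
            break
    return chosen


# ---------------------------------------------------------------------------
# Doppler color extraction
# ---------------------------------------------------------------------------
def hsv_in_red_range(h, s, v, ranges: HsvRanges = DEFAULT_HSV_RANGES):
    """Elementwise red-flow test on OpenCV-scaled HSV values."""
    h = np.asarray(h, dtype=float)
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    hue_ok = ((h >= ranges.hue_low[0]) & (h <= ranges.hue_low[1])) | (
        (h >= ranges.hue_high[0]) & (h <= ranges.hue_high[1])
    )
    return (
        hue_ok
        & (s >= ranges.saturation[0])
        & (s <= ranges.saturation[1])
        & (v >= ranges.value[0])
        & (v <= ranges.value[1])
    )


def extract_red_regions(
    image,
    ranges: HsvRanges = DEFAULT_HSV_RANGES,
    min_area_px: int = 5,
) -> List[RedRegion]:
    """Red-flow connected components of a Doppler cross-section, largest first.

    ``image`` may be a :class:`~sonoservo.phantom.DopplerXPlaneFrame` (its
    cross-section plane is used) or an RGB array.  Components are 8-connected;
    regions smaller than ``min_area_px`` are dropped as color noise.  The
    returned list is sorted by decreasing area (ties row-major by centroid),
    i.e. it is the ``C_all`` ordering of the Doppler path.
    """
    from skimage.color import rgb2hsv
    from skimage.measure import label, regionprops

    rgb = image.cross_section if isinstance(image, DopplerXPlaneFrame) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an RGB color image")
    rgb = rgb[:, :, :3]
    mask = np.zeros(rgb.shape[:2], dtype=bool)
    # exact prefilter: red hues require R to be the strict channel maximum,
    # so the HSV conversion only needs to run on the bounding box of R>G, R>B
    pre = (rgb[..., 0] > rgb[..., 1]) & (rgb[..., 0] > rgb[..., 2])
    if pre.any():
        rows = np.nonzero(pre.any(axis=1))[0]
        cols = np.nonzero(pre.any(axis=0))[0]
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        hsv = rgb2hsv(rgb[r0:r1, c0:c1])
        mask[r0:r1, c0:c1] = hsv_in_red_range(
            hsv[..., 0] * 180.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0, ranges
        )
    labels = label(mask, connectivity=2)
    regions = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        cy, cx = prop.centroid
        regions.append(
            RedRegion(centroid_px=(float(cx), float(cy)), area_px=int(prop.area), bbox=prop.bbox)
        )
    regions.sort(key=lambda r: (-r.area_px, r.centroid_px[1], r.centroid_px[0]))
    return regions


def merge_clusters(regions: Sequence[RedRegion], T_cl: float = 50.0) -> List[VesselCandidate]:
    """Greedily merge nearby red regions into flow clusters.

    Starting from the largest unclaimed region, any remaining region whose
    centroid lies strictly within ``T_cl`` px of the current cluster centroid
    is absorbed (largest first), and the cluster centroid is recomputed as
    the area-weighted mean after each absorption; the scan repeats until no
    region is absorbable, then continues with the next largest unclaimed
    region.  Clusters are returned as candidates sorted by total area.
    """
    remaining = sorted(regions, key=lambda r: (-r.area_px, r.centroid_px[1], r.centroid_px[0]))
    clusters: List[VesselCandidate] = []
    while remaining:
        seed = remaining.pop(0)
        cx, cy = seed.centroid_px
        area = float(seed.area_px)
        absorbed = True
        while absorbed:
            absorbed = False
            for i, region in enumerate(remaining):
                rx, ry = region.centroid_px
                if np.hypot(rx - cx, ry - cy) < T_cl:
                    total = area + region.area_px
                    cx = (cx * area + rx * region.area_px) / total
                    cy = (cy * area + ry * region.area_px) / total
                    area = total
                    remaining.pop(i)
                    absorbed = True
                    break
        clusters.append(VesselCandidate(position_px=(cx, cy), score=area))
    clusters.sort(key=lambda c: (-c.score, c.position_px[1], c.position_px[0]))
    for i, c in enumerate(clusters):
        c.rank = i + 1
    return clusters


# ---------------------------------------------------------------------------
# plausibility tracking
# ---------------------------------------------------------------------------
def update_vessel_position(
    candidates: Sequence[VesselCandidate],
    state: TrackerState,
    T_d: float = 50.0,
    frame_index: int | None = None,
) -> TrackerState:
    """Plausibility update of the vessel center P^t.

    Accepts the candidate nearest P^{t-1} when it lies within ``T_d`` px;
    otherwise (all candidates too far, or none at all) the previous center is
    retained.  Mutates and returns ``state``; appends to its history.
    """
    if state.position_px is None:
        raise TrackerNotInitializedError(
            "tracker has no initial vessel position; the operator must select "
            "the vessel cross-section at the scan start"
        )
    if frame_index is None:
        frame_index = state.last_update_frame + 1
    px, py = state.position_px
    accepted = False
    new_pos = state.position_px
    if candidates:
        dists = [np.hypot(c.position_px[0] - px, c.position_px[1] - py) for c in candidates]
        best = int(np.argmin(dists))
        if dists[best] <= T_d:
            new_pos = (float(candidates[best].position_px[0]), float(candidates[best].position_px[1]))
            accepted = True
    state.position_px = new_pos
    state.last_update_frame = frame_index
    state.history.append((frame_index, new_pos, accepted))
    return state


def write_history_csv(state: TrackerState, path, method: str = "doppler") -> None:
    """Export the tracker's per-frame decisions as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "method", "x_px", "y_px", "accepted"])
        for frame, pos, accepted in state.history:
            writer.writerow([frame, method, pos[0], pos[1], accepted])


def track_frame(
    frame,
    method: str,
    state: TrackerState,
    params: TrackingParams = TrackingParams(),
    template: Template | None = None,
    hsv_ranges: HsvRanges = DEFAULT_HSV_RANGES,
    frame_index: int | None = None,
    search_halfwidth_px: float | None = None,
) -> TrackerState:
    """Run one detector + plausibility update on a frame.

    ``method`` is ``"template"`` (requires ``template`` and a B-mode frame)
    or ``"doppler"`` (Doppler cross-section).  For the template path an
    optional ``search_halfwidth_px`` restricts the NCC search to a window
    around P^{t-1}; any window at least ``T_d`` + template half-size wide
    yields decisions identical to a full-image search, because farther
    candidates could never pass the distance gate.
    """
    if method == "template":
        if template is None:
            raise ValueError("template matching requires a template")
        img = frame.pixels if isinstance(frame, BModeFrame) else np.asarray(frame)
        offset = (0, 0)
        if search_halfwidth_px is not None and state.position_px is not None:
            th, tw = template.shape
            half_w = int(np.ceil(search_halfwidth_px)) + tw // 2
            half_h = int(np.ceil(search_halfwidth_px)) + th // 2
            cx, cy = (int(round(v)) for v in state.position_px)
            x0 = max(0, min(cx - half_w, img.shape[1] - tw))
            y0 = max(0, min(cy - half_h, img.shape[0] - th))
            x1 = min(img.shape[1], max(cx + half_w + 1, x0 + tw))
            y1 = min(img.shape[0], max(cy + half_h + 1, y0 + th))
            img = img[y0:y1, x0:x1]
            offset = (x0, y0)
        cmap = match_template(img, template)
        cmap.offset_px = offset
        candidates = rank_template_candidates(cmap, n=params.n_candidates)
    elif method == "doppler":
        regions = extract_red_regions(frame, ranges=hsv_ranges, min_area_px=params.min_region_area_px)
        candidates = merge_clusters(regions, T_cl=params.T_cl_px)[: params.n_candidates]
    else:
        raise ValueError(f"unknown tracking method {method!r}")
    return update_vessel_position(candidates, state, T_d=params.T_d_px, frame_index=frame_index)
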