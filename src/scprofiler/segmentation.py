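"""Centerline extraction: blur, Otsu binarization, skeletonization, line
tracing with breakpoints, and smoothing-spline fits.

The guide channel (central element in 2-channel mode, or the merge-blurred
axis channel in 1-channel mode) is reduced to ordered 1-pixel centerlines;
each line is fitted with a cubic smoothing spline parameterized by
normalized cumulative chord length, which supplies positions (nm) and unit
tangent directions for perpendicular profiling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import interpolate, ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io import ChannelImage, PipelineConfig

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
# fixed scan order makes tracing deterministic
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def blur(image: ChannelImage, sigma_px: float) -> ChannelImage:
    """Gaussian blur with reflective boundaries (intensity-conserving away
    from borders)."""
    if not sigma_px > 0:
        raise ValueError("sigma_px must be > 0")
    out = ndimage.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    return image.with_pixels(out)


def otsu_binarize(image: ChannelImage | np.ndarray) -> np.ndarray:
    """Binarize by Otsu's threshold over a 256-bin intensity histogram.

    Pixels strictly above the threshold map to foreground.  A constant image
    has no between-class variance to maximize and is rejected.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    if np.ptp(pixels) == 0:
        raise ValueError("degenerate intensity distribution (constant image)")
    thr = threshold_otsu(pixels, nbins=256)
    return pixels > thr


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Reduce a binary mask to 1-pixel-wide centerlines (Lee's method).

    The skeleton is a subset of the input foreground and preserves its
    topology (connected components and holes).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _skimage_skeletonize(mask, method="lee").astype(bool)


@dataclasses.dataclass
class TracedLine:
    """An ordered run of 8-adjacent skeleton pixels with no repeats."""

    coords: np.ndarray  # (m, 2) int array of (row, col)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)

    def __len__(self) -> int:
        return len(self.coords)


@dataclasses.dataclass
class TraceResult:
    lines: list[TracedLine]
    n_junction_px: int
    n_discarded_px: int  # pixels of lines shorter than the length cutoff


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def _walk_path(work: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Walk a degree-<=2 component from ``start``, consuming its pixels."""
    path = [start]
    work[start] = False
    current = start
    h, w = work.shape
    while True:
        nxt = None
        r, c = current
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and work[rr, cc]:
                nxt = (rr, cc)
                break
        if nxt is None:
            return path
        work[nxt] = False
        path.append(nxt)
        current = nxt


def _chord_angles(coords: np.ndarray, chord: int) -> np.ndarray:
    """Turn angle (deg) between successive ``chord``-pixel chords at each
    interior index; 0 where undefined."""
    m = len(coords)
    angles = np.zeros(m)
    if m < 2 * chord + 1:
        return angles
    pts = coords.astype(float)
    for i in range(chord, m - chord):
        v1 = pts[i] - pts[i - chord]
        v2 = pts[i + chord] - pts[i]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
        angles[i] = np.degrees(np.arccos(cosang))
    return angles


def _split_at_corners(
    path: list[tuple[int, int]], breakpoint_angle_deg: float, chord: int = 5
) -> list[np.ndarray]:
    coords = np.array(path, dtype=int)
    angles = _chord_angles(coords, chord)
    over = angles > breakpoint_angle_deg
    if not over.any():
        return [coords]
    # break only at local maxima of the turn angle so one corner yields one break
    breaks = []
    idxs = np.flatnonzero(over)
    for i in idxs:
        lo = max(0, i - chord)
        hi = min(len(angles), i + chord + 1)
        if angles[i] >= angles[lo:hi].max() and (not breaks or i - breaks[-1] > chord):
            breaks.append(i)
    segments = []
    start = 0
    for b in breaks:
        segments.append(coords[start : b + 1])  # break pixel goes to the earlier line
        start = b + 1
    segments.append(coords[start:])
    return [s for s in segments if len(s) > 0]


def trace_lines_full(
    skeleton: np.ndarray,
    breakpoint_angle_deg: float = 60.0,
    min_line_length_px: int = 10,
) -> TraceResult:
    """Order skeleton pixels into lines, breaking at junctions and corners.

    Junction pixels (more than 2 skeleton neighbors) belong to no line.
    Remaining pixels form simple paths or cycles which are walked end to
    end, then split wherever the direction change between successive
    5-pixel chords exceeds ``breakpoint_angle_deg``.  Lines shorter than
    ``min_line_length_px`` are dropped (their pixel count is reported).
    Pixel bookkeeping is exact:
    ``sum(len(line)) + n_discarded_px + n_junction_px == skeleton.sum()``.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        return TraceResult([], 0, 0)
    counts = _neighbor_counts(skel)
    junctions = skel & (counts > 2)
    work = skel & ~junctions
    n_junction = int(junctions.sum())

    remaining = work.copy()
    wcounts = _neighbor_counts(work)
    # endpoints first (deterministic scan order), then any leftover cycles
    endpoints = np.argwhere(work & (wcounts <= 1))
    paths: list[list[tuple[int, int]]] = []
    for r, c in endpoints:
        if remaining[r, c]:
            paths.append(_walk_path(remaining, (int(r), int(c))))
    while remaining.any():
        r, c = np.argwhere(remaining)[0]
        paths.append(_walk_path(remaining, (int(r), int(c))))

    lines: list[TracedLine] = []
    n_discarded = 0
    for path in paths:
        for seg in _split_at_corners(path, breakpoint_angle_deg):
            if len(seg) >= min_line_length_px:
                lines.append(TracedLine(seg))
            else:
                n_discarded += len(seg)
    return TraceResult(lines, n_junction, n_discarded)


def trace_lines(
    skeleton: np.ndarray,
    breakpoint_angle_deg: float = 60.0,
    min_line_length_px: int = 10,
) -> list[TracedLine]:
    return trace_lines_full(skeleton, breakpoint_angle_deg, min_line_length_px).lines


class CenterSpline:
    """Cubic smoothing spline through an ordered centerline.

    Parameterized by normalized cumulative chord length ``t in [0, 1]``;
    evaluates to positions in nm (row, col order) and unit tangents.
    """

    def __init__(self, tck, pixel_size_nm: float, n_samples: int):
        self._tck = tck
        self.pixel_size_nm = float(pixel_size_nm)
        self.n_samples = int(n_samples)

    def evaluate(self, t) -> np.ndarray:
        """Positions in nm, shape (..., 2) as (row_nm, col_nm)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        r, c = interpolate.splev(t, self._tck)
        return np.stack([r, c], axis=-1) * self.pixel_size_nm

    def tangent(self, t) -> np.ndarray:
        """Unit tangent vectors along increasing t, shape (..., 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dr, dc = interpolate.splev(t, self._tck, der=1)
        v = np.stack([dr, dc], axis=-1)
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        return v / norm

    def arc_length_nm(self, n: int = 512) -> float:
        pts = self.evaluate(np.linspace(0.0, 1.0, n))
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=-1)))


def fit_center_spline(
    line: TracedLine | np.ndarray,
    smoothing: float = 1.0,
    pixel_size_nm: float = 1.0,
) -> CenterSpline:
    """Fit a cubic smoothing spline to an ordered centerline.

    ``smoothing`` is the target RMS residual in pixels; internally the
    spline smoothing condition is ``s = m * smoothing**2`` (pixel^2 units)
    so the residual scale is independent of line length.  ``smoothing=0``
    interpolates.
    """
    coords = line.coords if isinstance(line, TracedLine) else np.asarray(line)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 4:
        raise ValueError("need an ordered (m, 2) line with at least 4 points")
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(steps == 0):
        keep = np.concatenate([[True], steps > 0])
        coords = coords[keep]
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if len(coords) < 4:
            raise ValueError("too few distinct points after deduplication")
    u = np.concatenate([[0.0], np.cumsum(steps)])
    u /= u[-1]
    s = len(coords) * float(smoothing) ** 2
    tck, _ = interpolate.splprep(
        [coords[:, 0], coords[:, 1]], u=u, s=s, k=3
    )
    return CenterSpline(tck, pixel_size_nm, n_samples=len(coords))


def extract_center_splines(
    guide: ChannelImage, config: PipelineConfig
) -> list[CenterSpline]:
    """Standard chain for the guide channel: blur, Otsu, skeletonize, trace,
    spline fit.  Lines too short to constrain a cubic are skipped."""
    blurred = blur(guide, config.blur_sigma_px)
    mask = otsu_binarize(blurred)
    if not mask.any():
        raise ValueError("no foreground after thresholding")
    skel = skeletonize(mask)
    lines = trace_lines(
        skel, config.breakpoint_angle_deg, config.min_line_length_px
    )
    splines = []
    for ln in lines:
        if len(ln) >= 4:
            splines.append(
                fit_center_spline(ln, config.spline_smoothing, guide.pixel_size_nm)
            )
    return splines


def estimate_axis_one_channel(
    axis_image: ChannelImage, config: PipelineConfig
) -> list[CenterSpline]:
    """Estimate the midline of a two-strand structure from the axis channel
    alone ('1 channel' mode).

    The axis channel is blurred with sigma = max_distance_nm / (2 * pixel
    size) so the two strands merge into a single ridge whose local
    transverse center of mass is the midline; the merged ridge is then
    binarized, skeletonized, traced and spline-fitted as usual.
    """
    merge_sigma_px = config.max_distance_nm / (2.0 * axis_image.pixel_size_nm)
    merged = blur(axis_image, merge_sigma_px)
    mask = otsu_binarize(merged)
    if not mask.any():
        raise ValueError("no foreground after thresholding")
    skel = skeletonize(mask)
    lines = trace_lines(
        skel, config.breakpoint_angle_deg, config.min_line_length_px
    )
    splines = []
    for ln in lines:
        if len(ln) >= 4:
            splines.append(
                fit_center_spline(
                    ln, config.spline_smoothing, axis_image.pixel_size_nm
                )
            )
    return splines
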