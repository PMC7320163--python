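"""Ground-truth image synthesis.

Renders the twisted two-strand validation helix (maximum-intensity
projection ``y_{1,2}(x) = +/- (a/2) * cos(b x)`` about the midline, so the
maximum center-to-center separation equals ``a``), straight parallel-ridge
oracles, and binary unit-test shapes.  Curves are drawn by arc-length
sampling with bilinear splatting before PSF convolution, which avoids the
aliasing a naive per-column rasterization would introduce into peak
positions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .io import ChannelImage


@dataclasses.dataclass
class HelixSpec:
    """Ground-truth parameters of a rendered validation helix.

    ``a_nm`` is the maximum center-to-center strand separation, ``b_per_nm``
    the angular frequency (strand crossings every ``pi/b`` nm along the
    axis).  Defaults reproduce the canonical validation: a = 800 nm,
    b = 1/1612 nm^-1, pixel size 32.24 nm, rendered over ~3 periods with a
    40 nm PSF and no noise.
    """

    a_nm: float = 800.0
    b_per_nm: float = 1.0 / 1612.0
    length_nm: float = 32000.0
    pixel_size_nm: float = 32.24
    psf_sigma_nm: float = 40.0
    height_nm: float = 2800.0
    amplitude: float = 1000.0
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_nm < 0:
            raise ValueError("a_nm must be >= 0")
        if not self.b_per_nm > 0:
            raise ValueError("b_per_nm must be > 0")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.a_nm > 0 and self.pixel_size_nm > self.a_nm / 4.0:
            raise ValueError(
                "undersampled: pixel size exceeds a quarter of the strand "
                "separation"
            )
        if self.length_nm <= 2.0 * math.pi / self.b_per_nm:
            raise ValueError("length_nm must exceed one period (2*pi/b)")
        min_height = self.a_nm + 6.0 * self.psf_sigma_nm
        if self.height_nm < min_height:
            raise ValueError(f"height_nm must be >= {min_height:.1f}")
        if self.psf_sigma_nm < 0 or self.noise_sd < 0 or self.background < 0:
            raise ValueError("psf_sigma_nm, noise_sd, background must be >= 0")

    @property
    def crossings_x_nm(self) -> list[float]:
        """Axis positions where the two strands cross (cos(bx) = 0)."""
        out = []
        k = 0
        while True:
            x = (k + 0.5) * math.pi / self.b_per_nm
            if x >= self.length_nm:
                return out
            out.append(x)
            k += 1


def _splat_bilinear(canvas: np.ndarray, rows, cols, weights) -> None:
    """Deposit weights at fractional (row, col) positions, bilinearly
    spread over the four surrounding pixels; out-of-canvas mass is dropped."""
    h, w = canvas.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[ok], cc[ok]), (weights * wt)[ok])


def _draw_curve(
    canvas: np.ndarray,
    x_nm: np.ndarray,
    y_nm: np.ndarray,
    mid_row: float,
    pixel_size_nm: float,
) -> None:
    """Draw a curve (x along columns, y transverse about mid_row) with
    constant intensity per unit arc length (resampled at pixel/4 steps)."""
    ds_step = pixel_size_nm / 4.0
    seg = np.hypot(np.diff(x_nm), np.diff(y_nm))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_uniform = np.arange(0.0, s[-1], ds_step)
    xi = np.interp(s_uniform, s, x_nm)
    yi = np.interp(s_uniform, s, y_nm)
    rows = mid_row + yi / pixel_size_nm
    cols = xi / pixel_size_nm
    _splat_bilinear(canvas, rows, cols, np.full(len(s_uniform), ds_step))


def render_helix(spec: HelixSpec) -> tuple[ChannelImage, ChannelImage, dict]:
    """Render the two-strand helix and its central-element midline channel.

    Returns ``(axis, central, truth)`` where the truth record carries the
    separation ground truth, the midline row, and the strand-crossing
    positions.
    """
    px = spec.pixel_size_nm
    width = int(math.ceil(spec.length_nm / px))
    height = int(math.ceil(spec.height_nm / px)) | 1  # odd: midline on a row
    mid_row = height // 2

    x = np.arange(0.0, spec.length_nm, px / 16.0)
    half = 0.5 * spec.a_nm * np.cos(spec.b_per_nm * x)

    axis = np.zeros((height, width))
    _draw_curve(axis, x, +half, mid_row, px)
    _draw_curve(axis, x, -half, mid_row, px)
    central = np.zeros((height, width))
    _draw_curve(central, x, np.zeros_like(x), mid_row, px)

    rng = np.random.default_rng(spec.seed)
    channels = []
    for canvas in (axis, central):
        if spec.psf_sigma_nm > 0:
            canvas = ndimage.gaussian_filter(canvas, spec.psf_sigma_nm / px)
        peak = canvas.max()
        if peak > 0:
            canvas = canvas * (spec.amplitude / peak)
        canvas = canvas + spec.background
        if spec.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
        channels.append(np.clip(canvas, 0.0, None))

    truth = {
        "a_nm": spec.a_nm,
        "b_per_nm": spec.b_per_nm,
        "length_nm": spec.length_nm,
        "pixel_size_nm": px,
        "psf_sigma_nm": spec.psf_sigma_nm,
        "midline_row": mid_row,
        "crossings_x_nm": spec.crossings_x_nm,
        "seed": spec.seed,
    }
    return (
        ChannelImage(channels[0], px, role="axis"),
        ChannelImage(channels[1], px, role="central"),
        truth,
    )


def render_parallel_ridges(
    separation_nm: float,
    length_nm: float,
    pixel_size_nm: float,
    psf_sigma_nm: float,
    height_nm: float = 2800.0,
    amplitude: float = 1000.0,
) -> ChannelImage:
    """Two straight horizontal ridges at +/- separation/2 about the image
    midline -- the closed-form oracle fixture for profile extraction."""
    if not separation_nm > 2.0 * pixel_size_nm:
        raise ValueError("separation_nm must exceed 2 pixels")
    if length_nm <= 0 or height_nm <= separation_nm:
        raise ValueError("degenerate canvas geometry")
    px = pixel_size_nm
    width = int(math.ceil(length_nm / px))
    height = int(math.ceil(height_nm / px)) | 1
    mid_row = height // 2
    canvas = np.zeros((height, width))
    x = np.arange(0.0, length_nm, px / 16.0)
    for sign in (+1.0, -1.0):
        y = np.full_like(x, sign * separation_nm / 2.0)
        if psf_sigma_nm > 0:
            _draw_curve(canvas, x, y, mid_row, px)
        else:
            # without a PSF keep the ridge a single pixel wide
            row = int(round(mid_row + sign * separation_nm / 2.0 / px))
            canvas[row, : width] += 1.0
    if psf_sigma_nm > 0:
        canvas = ndimage.gaussian_filter(canvas, psf_sigma_nm / px)
    peak = canvas.max()
    if peak > 0:
        canvas = canvas * (amplitude / peak)
    return ChannelImage(canvas, px, role="axis")


def render_shape(kind: str, **params) -> np.ndarray:
    """Deterministic binary fixtures: ring, open_c, L, T, bar.

    Common parameter: ``canvas=(rows, cols)``.  Shapes are centered and
    must fit inside the canvas.
    """
    canvas = params.pop("canvas", (64, 64))
    h, w = canvas
    out = np.zeros((h, w), dtype=bool)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]

    if kind in ("ring", "open_c"):
        outer = params.pop("outer_radius", 25)
        inner = params.pop("inner_radius", 18)
        if outer <= inner or inner < 0:
            raise ValueError("need outer_radius > inner_radius >= 0")
        if outer > min(cy, cx):
            raise ValueError("shape exceeds canvas")
        r = np.hypot(yy - cy, xx - cx)
        out = (r <= outer) & (r > inner)
        if kind == "open_c":
            gap_deg = params.pop("gap_deg", 60.0)
            ang = np.degrees(np.arctan2(yy - cy, xx - cx))
            out &= ~(np.abs(ang) <= gap_deg / 2.0)
    elif kind == "bar":
        length = params.pop("length", 50)
        thickness = params.pop("thickness", 5)
        if length > w or thickness > h:
            raise ValueError("shape exceeds canvas")
        r0 = int(cy - thickness // 2)
        c0 = int(cx - length // 2)
        out[r0 : r0 + thickness, c0 : c0 + length] = True
    elif kind == "L":
        arm = params.pop("arm", 40)
        thickness = params.pop("thickness", 1)
        if arm + 2 > min(h, w):
            raise ValueError("shape exceeds canvas")
        r0, c0 = 1, 1
        out[r0, c0 : c0 + arm] = True  # horizontal arm
        out[r0 : r0 + arm, c0] = True  # vertical arm
        if thickness > 1:
            out = ndimage.binary_dilation(out, iterations=thickness - 1)
    elif kind == "T":
        arm = params.pop("arm", 40)
        if arm + 4 > min(h, w):
            raise ValueError("shape exceeds canvas")
        r0 = 2
        c_mid = int(cx)
        out[r0, c_mid - arm // 2 : c_mid + arm // 2 + 1] = True
        out[r0 + 1 : r0 + 1 + arm, c_mid] = True
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    if params:
        raise ValueError(f"unused parameters: {sorted(params)}")
    return out
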