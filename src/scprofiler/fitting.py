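"""Distance histogramming, the half-normal edge fit, and single-Gaussian
width fits.

A 2D projection of a twisted two-strand structure can only underestimate
the true strand separation, so the per-profile distances pile up against a
hard edge at the true value.  The half-normal model is zero on one side of
the center ``c`` and ``A*exp(-(x-c)^2/(2*sigma^2)) + n`` on the other; its
fitted center is the reported strand distance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit
from scipy.special import erf

from .profiling import LineProfile

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass
class DistanceHistogram:
    """Uniform half-open bins ``[lo, hi)`` over kept distances (nm)."""

    bin_edges_nm: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_nm = np.asarray(self.bin_edges_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges_nm) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        widths = np.diff(self.bin_edges_nm)
        if widths.min() <= 0 or np.ptp(widths) > 1e-9:
            raise ValueError("edges must increase with uniform width")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def centers_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    @property
    def bin_width_nm(self) -> float:
        return float(self.bin_edges_nm[1] - self.bin_edges_nm[0])


@dataclasses.dataclass
class HalfNormFit:
    """Parameters of the half-normal histogram fit.

    ``c`` (nm) is the reported strand distance; ``sigma`` the Gaussian
    spread of the flank; ``n`` an additive count floor; ``c_stderr`` the
    covariance-derived standard error of ``c``.
    """

    A: float
    c: float
    sigma: float
    n: float
    c_stderr: float
    converged: bool
    fit_window_nm: tuple[float, float]


@dataclasses.dataclass
class GaussianFitResult:
    amplitude: float
    mean_nm: float
    sd_nm: float
    offset: float

    @property
    def fwhm_nm(self) -> float:
        return FWHM_FACTOR * self.sd_nm


def histogram_distances(
    distances_nm, bin_nm: float, range_nm: tuple[float, float]
) -> DistanceHistogram:
    """Bin distances into uniform half-open bins covering ``[lo, hi)``.

    Distances outside the range are excluded (they were already filtered
    upstream); a boundary value falls into the bin it opens.
    """
    d = np.asarray(list(distances_nm), dtype=float)
    if d.size == 0:
        raise ValueError("no distances to histogram")
    if not bin_nm > 0:
        raise ValueError("bin_nm must be > 0")
    lo, hi = range_nm
    if not hi > lo:
        raise ValueError("range must satisfy hi > lo")
    nbins = int(np.ceil((hi - lo) / bin_nm))
    edges = lo + np.arange(nbins + 1) * bin_nm
    sel = (d >= lo) & (d < edges[-1])
    counts, _ = np.histogram(d[sel], bins=edges)
    return DistanceHistogram(edges, counts)


def half_norm_model(
    x, A: float, c: float, sigma: float, n: float, tail: str = "left"
) -> np.ndarray:
    """Half-normal edge model.

    ``tail="left"`` places the Gaussian flank over ``x <= c`` (the data
    side for underestimate-skewed distance histograms) and is zero for
    ``x > c``; ``tail="right"`` is the mirror image.
    """
    x = np.asarray(x, dtype=float)
    g = A * np.exp(-((x - c) ** 2) / (2.0 * sigma**2)) + n
    if tail == "left":
        return np.where(x > c, 0.0, g)
    if tail == "right":
        return np.where(x < c, 0.0, g)
    raise ValueError("tail must be 'left' or 'right'")


def _bin_averaged_model(
    edges: np.ndarray, A: float, c: float, sigma: float, n: float, tail: str
) -> np.ndarray:
    """Expected count per bin: the half-normal model integrated over each
    bin and divided by the bin width.

    Integrating (rather than evaluating at bin centers) keeps the edge
    position ``c`` identifiable to sub-bin precision: the bin containing
    ``c`` is partially filled in proportion to where ``c`` cuts it.
    """
    s2 = sigma * np.sqrt(2.0)
    amp = A * sigma * np.sqrt(np.pi / 2.0)
    lo = edges[:-1]
    hi = edges[1:]
    if tail == "left":
        u = np.minimum(hi, c)
        length = np.clip(u - lo, 0.0, None)
        gauss = amp * (erf((c - lo) / s2) - erf((c - u) / s2))
        integral = np.where(length > 0, n * length + gauss, 0.0)
    else:
        v = np.maximum(lo, c)
        length = np.clip(hi - v, 0.0, None)
        gauss = amp * (erf((hi - c) / s2) - erf((v - c) / s2))
        integral = np.where(length > 0, n * length + gauss, 0.0)
    return integral / (hi - lo)


def fit_half_norm(
    hist: DistanceHistogram,
    fit_window_nm: tuple[float, float] | None = None,
    tail: str = "left",
) -> HalfNormFit:
    """Least-squares fit of the half-normal model to histogram counts.

    The model prediction for each bin is the bin-averaged integral of the
    half-normal, so the fitted center ``c`` resolves the histogram's edge
    to sub-bin precision.  By default the fit window spans the whole
    histogram, which is needed to identify the flank parameters A, sigma
    and the floor n (a narrow window around the peak leaves them
    degenerate); pass ``fit_window_nm`` to restrict.  Initialization: ``c0`` =
    tallest-bin center, ``A0`` = max count, ``sigma0`` = 2 bins, ``n0`` =
    median count in the window.  Bounded trust-region least squares
    (A, sigma > 0, n >= 0, c within the data span); non-convergence is
    reported via the flag, not raised.
    """
    centers = hist.centers_nm
    counts = hist.counts.astype(float)
    w = hist.bin_width_nm
    if int((counts > 0).sum()) < 5:
        raise ValueError("too few non-empty bins (need >= 5)")
    if fit_window_nm is None:
        lo = float(hist.bin_edges_nm[0])
        hi = float(hist.bin_edges_nm[-1])
    else:
        lo, hi = fit_window_nm
    win = (centers >= lo) & (centers <= hi)
    xw, yw = centers[win], counts[win]
    edges_w = np.concatenate([xw - w / 2.0, [xw[-1] + w / 2.0]])
    if len(xw) < 5:
        raise ValueError("fit window contains too few bins (need >= 5)")

    imax = int(np.argmax(yw))
    A0 = float(max(yw.max(), 1.0))
    sigma0 = 2.0 * w
    n0 = float(np.median(yw))
    span_lo, span_hi = float(edges_w[0]), float(edges_w[-1])
    bounds = (
        [0.0, span_lo, 1e-6, 0.0],
        [np.inf, span_hi, np.inf, np.inf],
    )
    # the edge lies at or beyond the dominant bin; multistart over a few
    # candidate centers avoids sub-bin local minima of the piecewise model
    rightmost = float(xw[np.flatnonzero(yw > 0)[-1]])
    c_starts = sorted({float(xw[imax]), float(xw[imax]) + w, rightmost})

    def model(_x, A, c, sigma, n):
        return _bin_averaged_model(edges_w, A, c, sigma, n, tail)

    best = None
    for c0 in c_starts:
        p0 = [A0, min(max(c0, span_lo), span_hi), sigma0, max(n0, 0.0)]
        try:
            popt, pcov = curve_fit(
                model, xw, yw, p0=p0, bounds=bounds, maxfev=1000 * len(p0),
                xtol=1e-10, ftol=1e-10,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((model(xw, *popt) - yw) ** 2))
        if best is None or cost < best[0]:
            best = (cost, popt, pcov)
    converged = best is not None
    if converged:
        _, popt, pcov = best
        c_stderr = (
            float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
        )
    else:
        popt = [A0, float(xw[imax]), sigma0, max(n0, 0.0)]
        c_stderr = float("nan")
    A, c, sigma, n = (float(v) for v in popt)
    if not (span_lo <= c <= span_hi) or not np.isfinite(c):
        converged = False
    return HalfNormFit(
        A=A, c=c, sigma=sigma, n=n, c_stderr=c_stderr,
        converged=converged, fit_window_nm=(lo, hi),
    )


def fit_gaussian_profile(profile: LineProfile) -> GaussianFitResult:
    """Fit ``offset + amplitude * exp(-(x-mean)^2/(2*sd^2))`` to a
    monomodal profile; reports sd and (via the result) FWHM.

    A profile with two local maxima whose prominences both exceed 20% of
    the intensity range is rejected as bimodal.
    """
    x = profile.offsets_nm
    y = profile.intensities
    rng = float(np.ptp(y))
    if rng == 0:
        raise ValueError("flat profile")
    peaks, props = signal.find_peaks(y, prominence=0.2 * rng)
    if len(peaks) >= 2:
        raise ValueError("profile not monomodal")

    offset0 = float(y.min())
    amp0 = float(y.max() - y.min())
    mean0 = float(x[np.argmax(y)])
    weights = np.clip(y - offset0, 0, None)
    wsum = weights.sum()
    sd0 = (
        float(np.sqrt(np.sum(weights * (x - mean0) ** 2) / wsum))
        if wsum > 0
        else float(np.ptp(x)) / 4.0
    )
    sd0 = max(sd0, (x[1] - x[0]))

    def model(x, amplitude, mean, sd, offset):
        return offset + amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))

    popt, _ = curve_fit(
        model, x, y,
        p0=[amp0, mean0, sd0, offset0],
        bounds=([0.0, x[0], 1e-9, 0.0], [np.inf, x[-1], np.inf, np.inf]),
        maxfev=4000,
    )
    amplitude, mean, sd, offset = (float(v) for v in popt)
    return GaussianFitResult(amplitude, mean, sd, offset)
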