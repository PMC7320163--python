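"""Image, configuration and result I/O.

All raster input is plain TIFF (single- or multi-page, integer or float,
grayscale per channel).  The physical pixel size is always an explicit user
input: resolution tags written by SIM/ExM export pipelines are unreliable, so
when a file carries them *and* the caller supplies a pixel size, the caller
wins and a warning is logged.

Coordinate convention used throughout the package: 0-based ``(row, col)``
indices, pixel centers at integer coordinates, physical position
``nm = index * pixel_size_nm``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("scprofiler")

ROLES = ("axis", "central", "generic")

try:
    __version__ = _pkg_version("scprofiler")
except PackageNotFoundError:  # pragma: no cover - editable/dev corner case
    __version__ = "0+unknown"


@dataclasses.dataclass
class ChannelImage:
    """A single-channel 2D intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size_nm
        Edge length of one (isotropic) pixel in nanometres.
    role
        Which channel this grid represents: ``"axis"`` for the strand
        protein (e.g. SYCP3), ``"central"`` for a central-element protein
        (e.g. SYCE3), or ``"generic"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    role: str = "generic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not float(self.pixel_size_nm) > 0:
            raise ValueError("pixel_size_nm must be > 0")
        self.pixel_size_nm = float(self.pixel_size_nm)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Same metadata, new intensity grid."""
        return ChannelImage(pixels, self.pixel_size_nm, self.role)


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the measurement pipeline.

    Distances are in nm, lengths in pixels where noted.  The defaults target
    ~4x expanded SIM images of synaptonemal complexes; callers analysing
    unexpanded data must override ``min_distance_nm``/``max_distance_nm``.

    ``profile_step_nm=None`` resolves at run time to half the image pixel
    size.  ``fit_window_nm`` optionally overrides the automatic histogram
    fit window (see :func:`scprofiler.fitting.fit_half_norm`).
    """

    mode: str = "one_channel"  # or "two_channel"
    blur_sigma_px: float = 1.0
    min_distance_nm: float = 400.0
    max_distance_nm: float = 1200.0
    profile_halflength_nm: float = 1300.0
    profile_step_nm: float | None = None
    histogram_bin_nm: float = 10.0
    min_line_length_px: int = 10
    spline_smoothing: float = 1.0
    breakpoint_angle_deg: float = 60.0
    seed: int = 0
    fit_window_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("one_channel", "two_channel"):
            raise ValueError("mode must be 'one_channel' or 'two_channel'")
        if not self.blur_sigma_px > 0:
            raise ValueError("blur_sigma_px must be > 0")
        if self.min_distance_nm < 0:
            raise ValueError("min_distance_nm must be >= 0")
        if not self.max_distance_nm > self.min_distance_nm:
            raise ValueError("max_distance_nm must exceed min_distance_nm")
        if not self.profile_halflength_nm > 0:
            raise ValueError("profile_halflength_nm must be > 0")
        if self.profile_halflength_nm < self.max_distance_nm:
            # a bimodal pair at maximal separation must fit inside one profile
            raise ValueError(
                "profile_halflength_nm must be >= max_distance_nm"
            )
        if self.profile_step_nm is not None and not self.profile_step_nm > 0:
            raise ValueError("profile_step_nm must be > 0")
        if not self.histogram_bin_nm > 0:
            raise ValueError("histogram_bin_nm must be > 0")
        if self.min_line_length_px < 2:
            raise ValueError("min_line_length_px must be >= 2")
        if self.spline_smoothing < 0:
            raise ValueError("spline_smoothing must be >= 0")
        if not 0 < self.breakpoint_angle_deg < 180:
            raise ValueError("breakpoint_angle_deg must be in (0, 180)")
        if self.fit_window_nm is not None:
            lo, hi = self.fit_window_nm
            if not hi > lo:
                raise ValueError("fit_window_nm must be (lo, hi) with hi > lo")

    def resolve_step_nm(self, pixel_size_nm: float) -> float:
        return (
            self.profile_step_nm
            if self.profile_step_nm is not None
            else pixel_size_nm / 2.0
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "fit_window_nm" in kwargs and kwargs["fit_window_nm"] is not None:
            kwargs["fit_window_nm"] = tuple(kwargs["fit_window_nm"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "PipelineConfig":
        """Load a flat key-value (YAML) config file mirroring the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError("config file must contain a key-value mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["fit_window_nm"] is not None:
            d["fit_window_nm"] = list(d["fit_window_nm"])
        return d


@dataclasses.dataclass
class PipelineResult:
    """Everything the pipeline measures on one image.

    ``distances`` retains discarded measurements (with their reason) so that
    written tables are an audit trail, not just the kept subset.
    """

    per_line_average_profiles: list  # list[LineProfile]
    image_average_profile: object | None  # LineProfile | None
    distances: list  # list[ProfileDistance]
    histogram: object | None  # DistanceHistogram | None
    fit: object | None  # HalfNormFit | None
    counts: dict
    config: PipelineConfig

    @property
    def kept_distances_nm(self) -> list[float]:
        return [d.distance_nm for d in self.distances if d.kept]


def read_channels(
    path: str | pathlib.Path,
    channel_indices: Sequence[int],
    pixel_size_nm: float,
    roles: Sequence[str] | None = None,
) -> list[ChannelImage]:
    """Read the requested channels of a TIFF file.

    Multi-page and multi-sample TIFFs are treated alike: the leading axis of
    the stored array indexes channels.  Every requested page must be 2D; 3D
    stacks must be max-projected first (:func:`project_z`).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        res = tf.pages[0].tags.get("XResolution")
    if res is not None:
        logger.warning(
            "%s carries TIFF resolution metadata; using the supplied "
            "pixel size %.6g nm instead", path.name, pixel_size_nm,
        )
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3:
        pages = list(arr)
    else:
        raise ValueError(
            f"unsupported TIFF dimensionality {arr.ndim}; "
            "max-project 3D stacks first (project_z)"
        )
    out: list[ChannelImage] = []
    roles = list(roles) if roles is not None else ["generic"] * len(channel_indices)
    if len(roles) != len(channel_indices):
        raise ValueError("roles must match channel_indices in length")
    for idx, role in zip(channel_indices, roles):
        if not 0 <= idx < len(pages):
            raise IndexError(
                f"channel index out of range: {idx} (file has {len(pages)})"
            )
        page = np.asarray(pages[idx])
        if page.ndim != 2:
            raise ValueError("non-2D page; max-project 3D stacks first")
        if page.size == 0:
            raise ValueError("zero-size image page")
        out.append(ChannelImage(page, pixel_size_nm, role))
    shapes = {ci.shape for ci in out}
    if len(shapes) > 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    return out


def project_z(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (z) axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (z, row, col)")
    if stack.shape[0] < 1:
        raise ValueError("empty stack")
    return stack.max(axis=0)


def write_tiff(path: str | pathlib.Path, channels: Sequence[ChannelImage]) -> None:
    """Write channels as a multi-page float32 TIFF."""
    data = np.stack([c.pixels for c in channels]).astype(np.float32)
    tifffile.imwrite(path, data)


def _fit_to_dict(fit) -> dict | None:
    if fit is None:
        return None
    return {
        "A": fit.A,
        "c_nm": fit.c,
        "sigma_nm": fit.sigma,
        "n": fit.n,
        "c_stderr_nm": fit.c_stderr,
        "converged": bool(fit.converged),
        "fit_window_nm": list(fit.fit_window_nm),
    }


def write_results(result: PipelineResult, out_dir: str | pathlib.Path) -> dict:
    """Write distances.csv, profiles.csv and summary.json; return a manifest.

    distances.csv has one row per profile that was attempted (kept and
    discarded, flagged); profiles.csv holds the aligned average profiles in
    long format.  Floats are written with 8 significant digits.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, d in enumerate(result.distances):
        src = getattr(d, "source", None)
        rows.append(
            {
                "profile_id": i,
                "line_id": getattr(src, "line_id", -1) if src else -1,
                "source_row_px": src.pixel[0] if src else -1,
                "source_col_px": src.pixel[1] if src else -1,
                "distance_nm": d.distance_nm,
                "kept": bool(d.kept),
                "reason": d.reason,
            }
        )
    distances_csv = out_dir / "distances.csv"
    pd.DataFrame(
        rows,
        columns=[
            "profile_id", "line_id", "source_row_px", "source_col_px",
            "distance_nm", "kept", "reason",
        ],
    ).to_csv(distances_csv, index=False, float_format="%.8g")

    prows = []
    profiles = list(result.per_line_average_profiles)
    if result.image_average_profile is not None:
        profiles = profiles + [result.image_average_profile]
    for prof in profiles:
        label = prof.source if isinstance(prof.source, str) else "profile"
        for off, inten in zip(prof.offsets_nm, prof.intensities):
            prows.append(
                {"profile_id": label, "offset_nm": off, "intensity": inten}
            )
    profiles_csv = out_dir / "profiles.csv"
    pd.DataFrame(
        prows, columns=["profile_id", "offset_nm", "intensity"]
    ).to_csv(profiles_csv, index=False, float_format="%.8g")

    hist = result.histogram
    summary = {
        "software": "scprofiler",
        "version": __version__,
        "fit": _fit_to_dict(result.fit),
        "counts": result.counts,
        "config": result.config.to_dict(),
        "histogram": None
        if hist is None
        else {
            "bin_edges_nm": [float(e) for e in hist.bin_edges_nm],
            "counts": [int(c) for c in hist.counts],
        },
    }
    summary_json = out_dir / "summary.json"
    with open(summary_json, "w") as fh:
        json.dump(summary, fh, indent=2)

    return {
        "distances_csv": str(distances_csv),
        "profiles_csv": str(profiles_csv),
        "summary_json": str(summary_json),
    }
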