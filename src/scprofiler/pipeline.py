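"""End-to-end measurement pipeline.

Chains the stages: blur -> Otsu -> skeletonize -> trace -> spline (from the
central-element channel in 2-channel mode, or from the merge-blurred axis
channel in 1-channel mode) -> floodfill on the axis channel -> source
selection -> perpendicular profiles -> peak-to-peak distances -> distance
filter -> histogram -> half-normal fit -> aligned averages.
"""

from __future__ import annotations

import logging

from .io import ChannelImage, PipelineConfig, PipelineResult
from .fitting import fit_half_norm, histogram_distances
from .profiling import (
    LineProfile,
    ProfileDistance,
    SourcePoint,
    align_and_average,
    extract_profile,
    filter_distances,
    find_enclosed_regions,
    peak_to_peak_distance,
    select_sources,
)
from .segmentation import (
    blur,
    estimate_axis_one_channel,
    extract_center_splines,
    otsu_binarize,
)

logger = logging.getLogger("scprofiler")


class AnalysisError(RuntimeError):
    """The image holds no measurable structure (degenerate input)."""


def measure_profiles(
    axis_image: ChannelImage,
    sources: list[SourcePoint],
    config: PipelineConfig,
) -> tuple[list[LineProfile | None], list[ProfileDistance]]:
    """Extract a perpendicular profile and its peak-to-peak distance for
    every source; out-of-bounds sources yield a ``None`` profile and an
    ``out_of_bounds`` record so the lists stay parallel."""
    profiles: list[LineProfile | None] = []
    distances: list[ProfileDistance] = []
    for src in sources:
        prof = extract_profile(axis_image, src, config)
        profiles.append(prof)
        if prof is None:
            distances.append(
                ProfileDistance(
                    float("nan"), False, "out_of_bounds", source=src
                )
            )
        else:
            distances.append(peak_to_peak_distance(prof))
    return profiles, distances


def run_pipeline(
    axis: ChannelImage,
    central: ChannelImage | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Measure strand distances on one image.

    ``axis`` is the strand-protein channel (always profiled); ``central``
    is the central-element guide channel, required in two_channel mode.
    """
    config = config or PipelineConfig()
    if min(axis.shape) < 16:
        raise AnalysisError("image too small for pipeline use (min 16x16)")
    if config.mode == "two_channel":
        if central is None:
            raise ValueError("two_channel mode requires a central channel")
        if central.shape != axis.shape:
            raise ValueError("axis and central channel shapes differ")

    try:
        if config.mode == "two_channel":
            splines = extract_center_splines(central, config)
        else:
            splines = estimate_axis_one_channel(axis, config)
    except ValueError as exc:
        raise AnalysisError(f"no foreground after thresholding ({exc})") from exc
    if not splines:
        raise AnalysisError("no measurable structures (no traceable lines)")
    logger.info("traced %d center lines", len(splines))

    try:
        axis_mask = otsu_binarize(blur(axis, config.blur_sigma_px))
    except ValueError as exc:
        raise AnalysisError(f"no foreground after thresholding ({exc})") from exc
    enclosed = find_enclosed_regions(axis_mask)
    sources = select_sources(splines, enclosed, axis.pixel_size_nm)
    logger.info("selected %d profile sources in enclosed regions", len(sources))
    if not sources:
        raise AnalysisError("no measurable structures (no enclosed regions)")

    blurred_axis = blur(axis, config.blur_sigma_px)
    profiles, raw_distances = measure_profiles(blurred_axis, sources, config)
    distances = filter_distances(raw_distances, config)

    n_extracted = sum(p is not None for p in profiles)
    n_kept = sum(d.kept for d in distances)
    n_discarded = sum(
        d.reason in ("below_min", "above_max") for d in distances
    )
    counts = {
        "lines_traced": len(splines),
        "sources_selected": len(sources),
        "profiles_extracted": n_extracted,
        "distances_kept": n_kept,
        "distances_discarded": n_discarded,
    }
    logger.info("profile counts: %s", counts)

    kept_values = [d.distance_nm for d in distances if d.kept]
    if not kept_values:
        raise AnalysisError("no distances within the configured bounds")

    hist = histogram_distances(
        kept_values,
        config.histogram_bin_nm,
        (config.min_distance_nm, config.max_distance_nm + config.histogram_bin_nm),
    )
    try:
        fit = fit_half_norm(hist, config.fit_window_nm)
    except ValueError as exc:
        logger.warning("half-norm fit skipped: %s", exc)
        fit = None

    per_line, overall = align_and_average(profiles, distances)

    return PipelineResult(
        per_line_average_profiles=per_line,
        image_average_profile=overall,
        distances=distances,
        histogram=hist,
        fit=fit,
        counts=counts,
        config=config,
    )
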