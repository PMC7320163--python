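"""Run the full 1-channel measurement pipeline on the validation helix.

The pipeline blurs and binarizes the strand channel, extracts the midline
by merge-blur + skeletonization, selects profile sources inside enclosed
(frontal-view) lobes, measures per-profile peak-to-peak distances
perpendicular to the midline, filters them to 400-1200 nm, and fits the
half-normal edge model to the distance histogram.  The fitted center c is
the strand distance; for the a = 800 nm helix it should land within
800 +/- 5 nm.
"""

from scprofiler import HelixSpec, render_helix, run_pipeline

axis, central, truth = render_helix(HelixSpec())
result = run_pipeline(axis)

print("stage counts:", result.counts)
fit = result.fit
print(f"strand distance c = {fit.c:.2f} +/- {fit.c_stderr:.2f} nm "
      f"(flank sigma = {fit.sigma:.1f} nm)")
print(f"ground truth a = {truth['a_nm']} nm -> error {fit.c - truth['a_nm']:+.2f} nm")
# c estimates the histogram's upper edge: 2D projection can only
# underestimate the 3D separation, so the true value sits at the edge.
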