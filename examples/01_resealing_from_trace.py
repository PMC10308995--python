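"""Measure a membrane resealing time from a single dye trace.

Builds one synthetic voltage-sensitive-dye trace (100 background frames,
380 post-laser frames at 1 frame/s) with a known resealing time of 75 s,
then runs the full per-cell analysis: photobleaching correction,
perforation call, and the 90%-recovery crossing time.
"""

from optopore import TraceSpec, analyze_trace, make_trace

spec = TraceSpec(perforated=True, dip_fraction=0.55,
                 true_resealing_time=75.0, bleach_slope=-0.03,
                 noise_sd=0.3, seed=7)
trace, truth = make_trace(spec)
result = analyze_trace(trace)

print(f"perforated call:        {result.perforated}")
print(f"dip depth (1 - min dF/F): {result.dip_depth:.3f}")
print(f"estimated resealing time: {result.resealing_time:.2f} s")
print(f"true resealing time:      {truth.true_resealing_time:.2f} s")
print(f"fitted bleach slope:      {result.bleach_slope:.4f} AU/frame")
# The estimate should sit within a frame of the 75 s ground truth: the
# dip recovers exponentially and the analysis interpolates the first
# confirmed crossing of 90% of the resting level.
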