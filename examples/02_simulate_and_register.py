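"""Simulate a raw time-stretch record and register its clock drift.

Builds a background-only record (the repeating laser-spectrum envelope
sampled by a free-running digitizer, plus detector noise), then estimates
the true samples-per-line ratio from the waveform alone and compares it
with the simulator's ground truth.
"""

from dataclasses import replace

from pixelsr import DEFAULT_CONFIG, coarse_ratio, refine_ratio, synth_record

cfg = replace(DEFAULT_CONFIG, n_lines=512)
rec = synth_record(None, cfg, noise_sd=0.02, ratio_perturb=3e-5, seed=42)
truth = rec.ground_truth.ratio

coarse = coarse_ratio(rec)
refined = refine_ratio(rec, coarse)

print(f"nominal f/F     : {cfg.ratio:.6f} samples/line")
print(f"true f/F        : {truth:.6f}  (clock perturbed by +3e-5 relative)")
print(f"coarse estimate : {coarse.ratio:.6f}  (err {coarse.ratio - truth:+.2e})")
print(f"refined estimate: {refined.ratio:.6f}  (err {refined.ratio - truth:+.2e})")
print(f"implied drift   : {refined.delta_x_hat:.3f} um/line, "
      f"tan(theta) = {refined.delta_x_hat / 0.18:.2f}")

# The refinement maximizes the sharpness of the interleaved line profile
# (evaluated at the line-rate harmonics of the record's spectrum); errors
# of a few 1e-5 samples/line keep sub-pixel registration coherent across
# hundreds of lines.
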