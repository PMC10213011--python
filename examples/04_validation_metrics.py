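"""Per-channel quality metrics: RMS contrast and median intensity.

RMS contrast is the population standard deviation of a channel's
intensities; median intensity is a robust brightness proxy.  Comparing
their across-frame variances before vs after processing quantifies how
much the pipeline harmonized the set.
"""

from benthic_ready.contrast import equalize_adaptive
from benthic_ready.synthetic import generate_transect
from benthic_ready.validation import median_intensity, rms_contrast

scenes = generate_transect(n=4, seed=19)

print(f"{'frame':44s} {'RMS contrast (R,G,B)':>26s} {'median (R,G,B)':>20s}")
for record, _ in scenes:
    enhanced = equalize_adaptive(record)
    c0 = rms_contrast(record).as_tuple()
    c1 = rms_contrast(enhanced).as_tuple()
    m0 = median_intensity(record).as_tuple()
    print(f"{record.filename:44s} "
          f"{c0[0]:5.1f},{c0[1]:5.1f},{c0[2]:5.1f} -> "
          f"{c1[0]:5.1f},{c1[1]:5.1f},{c1[2]:5.1f} "
          f"{m0[0]:6.1f},{m0[1]:5.1f},{m0[2]:5.1f}")
print()
print("Adaptive equalization raises RMS contrast in every channel; raw")
print("median intensities differ frame to frame because altitude varies.")
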