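"""Run the full preprocessing pipeline on a synthetic transect.

Stages in order: light-cone correction (batch z-score), contrast
enhancement (CLAHE), color normalization (histogram matching to the
frame closest to the seafloor), and footprint standardization (rescale
to the median scale, center-crop to the common minima).  Writes lossless
intermediates per stage plus a provenance manifest and validation report.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from benthic_ready.images import write_image
from benthic_ready.pipeline import PipelineConfig, run_pipeline
from benthic_ready.synthetic import SceneParams, generate_transect

with TemporaryDirectory() as tmp:
    raw_dir = Path(tmp) / "raw"
    raw_dir.mkdir()
    params = SceneParams(width_px=360, height_px=240, base_scale_px_per_cm_at_1m=15.0)
    for record, _ in generate_transect(n=10, seed=3, params=params):
        write_image(record, raw_dir / (Path(record.filename).stem + ".png"))

    config = PipelineConfig(
        input_dir=str(raw_dir),
        output_dir=str(Path(tmp) / "out"),
        laser_separation_cm=10.0,
    )
    result = run_pipeline(config)

    spec = result.spec
    print(f"analysis-ready frames : {len(result.manifest)}")
    print(f"common geometry       : {spec.target_height_px} x {spec.target_width_px} px "
          f"at {spec.target_scale_px_per_cm:.2f} px/cm")
    print(f"common footprint      : {spec.footprint_m2:.4f} m^2 per frame")
    v = result.report.variances
    print("across-frame variance of median intensity (R, G, B):")
    print("  before: " + "  ".join(f"{v[f'before.median_intensity_{c}']:.1f}" for c in "RGB"))
    print("  after : " + "  ".join(f"{v[f'after.median_intensity_{c}']:.3f}" for c in "RGB"))
    print(f"footprint variance    : {v['before.footprint_m2']:.4f} -> "
          f"{v['after.footprint_m2']:.4f} m^2")
print()
print("All outputs share one geometry (footprint variance exactly 0) and")
print("near-identical brightness, so frames are comparable sampling units.")
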