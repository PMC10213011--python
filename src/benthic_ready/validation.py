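"""Technical-validation metrics: per-channel contrast, brightness, footprint variance.

Whether the preprocessing achieved its goals is quantified with three
distributional statistics, each computed on decoded pixel buffers (never
after lossy re-encoding):

* RMS contrast — the population standard deviation of intensities per
  (R, G, B) channel; higher means more contrast.
* Median intensity — the per-channel median, a robust proxy for scene
  brightness.
* Footprint area — the physical seabed area covered by a frame, in m².

For a well-processed set, the across-image variance of each metric
collapses: contrast becomes uniformly high, brightness uniform, and the
footprint variance exactly zero (all frames share the same geometry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BenthicReadyError
from .footprint import FootprintSpec
from .images import ImageRecord

CHANNELS = ("R", "G", "B")


def population_variance(values) -> float:
    """Population variance, shifted by the first element for numerical exactness.

    Variance is shift-invariant; anchoring at ``values[0]`` makes the
    result exactly 0.0 for a constant list (a plain ``np.var`` can return
    ~1e-34 there from summation rounding) and avoids cancellation for
    large means.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("variance of an empty list is undefined")
    return float(np.var(x - x[0]))


@dataclass(frozen=True)
class ChannelStats:
    """One metric's value per color channel."""

    r: float
    g: float
    b: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)


def rms_contrast(image: ImageRecord) -> ChannelStats:
    """Population standard deviation of intensities, per channel."""
    px = image.pixels.astype(np.float64)
    stds = px.reshape(-1, 3).std(axis=0)
    return ChannelStats(*[float(s) for s in stds])


def median_intensity(image: ImageRecord) -> ChannelStats:
    """Median intensity per channel (even pixel counts average the central pair)."""
    px = image.pixels.astype(np.float64)
    meds = np.median(px.reshape(-1, 3), axis=0)
    return ChannelStats(*[float(m) for m in meds])


def footprint_area_m2(height_px: int, width_px: int, scale_px_per_cm: float) -> float:
    """Physical seabed area of a frame in square meters."""
    if scale_px_per_cm <= 0:
        raise ValueError("scale must be positive")
    return (height_px / scale_px_per_cm) * (width_px / scale_px_per_cm) / 1e4


@dataclass
class ValidationReport:
    """Per-image metrics and their across-image (population) variances.

    ``per_image`` has one row per image and set ("before"/"after") with the
    RMS contrast and median intensity per channel plus the footprint area.
    ``variances`` maps ``<set>.<metric>.<channel>`` to the across-image
    population variance; ``ratios`` holds after/before variance ratios
    (NaN where the before-variance is zero).
    """

    per_image: pd.DataFrame
    variances: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"variances": self.variances, "ratios": self.ratios}, fh, indent=2)


def _set_rows(name: str, images: list[ImageRecord], areas_m2: list[float]) -> list[dict]:
    rows = []
    for img, area in zip(images, areas_m2):
        contrast = rms_contrast(img)
        brightness = median_intensity(img)
        row = {"set": name, "image": img.filename}
        for ch, cv, bv in zip(CHANNELS, contrast.as_tuple(), brightness.as_tuple()):
            row[f"rms_contrast_{ch}"] = cv
            row[f"median_intensity_{ch}"] = bv
        row["footprint_m2"] = area
        rows.append(row)
    return rows


def dataset_variance_report(
    before: list[ImageRecord],
    before_scales_px_per_cm: list[float],
    after: list[ImageRecord],
    after_spec: FootprintSpec,
    paired: bool = False,
) -> ValidationReport:
    """Before/after comparison of contrast, brightness and footprint variances.

    ``before`` frames carry their own scales (one per image); ``after``
    frames all share the geometry of ``after_spec``.  With ``paired=True``
    the two sets must have equal length (same frames before and after).
    """
    if len(before) == 0 or len(after) == 0:
        raise BenthicReadyError("both image sets must be non-empty")
    if len(before) != len(before_scales_px_per_cm):
        raise BenthicReadyError(
            f"{len(before)} before-images but {len(before_scales_px_per_cm)} scales"
        )
    if paired and len(before) != len(after):
        raise BenthicReadyError(
            f"--paired requested but sets differ: {len(before)} vs {len(after)} images"
        )
    before_areas = [
        footprint_area_m2(img.height_px, img.width_px, s)
        for img, s in zip(before, before_scales_px_per_cm)
    ]
    after_areas = [after_spec.footprint_m2] * len(after)
    rows = _set_rows("before", before, before_areas) + _set_rows("after", after, after_areas)
    per_image = pd.DataFrame(rows)

    metric_cols = [c for c in per_image.columns if c not in ("set", "image")]
    variances: dict[str, float] = {}
    for name in ("before", "after"):
        sub = per_image[per_image["set"] == name]
        for col in metric_cols:
            # Population variance across images: the set itself is the
            # population being described, not a sample from one.
            variances[f"{name}.{col}"] = population_variance(sub[col].to_numpy())
    ratios = {}
    for col in metric_cols:
        b = variances[f"before.{col}"]
        a = variances[f"after.{col}"]
        ratios[col] = float(a / b) if b > 0 else float("nan")
    return ValidationReport(per_image=per_image, variances=variances, ratios=ratios)


def render_report_figure(report: ValidationReport, path) -> None:
    """Optional bar chart: channel-grouped before/after variances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["rms_contrast", "median_intensity"]
    fig, axes = plt.subplots(1, len(metrics) + 1, figsize=(4 * (len(metrics) + 1), 3.2))
    x = np.arange(len(CHANNELS))
    for ax, metric in zip(axes, metrics):
        bvals = [report.variances[f"before.{metric}_{ch}"] for ch in CHANNELS]
        avals = [report.variances[f"after.{metric}_{ch}"] for ch in CHANNELS]
        ax.bar(x - 0.2, bvals, width=0.4, label="before", color="#888")
        ax.bar(x + 0.2, avals, width=0.4, label="after", color="#2a7")
        ax.set_xticks(x, CHANNELS)
        ax.set_title(f"{metric} variance")
        ax.legend()
    ax = axes[-1]
    ax.bar([0, 1], [report.variances["before.footprint_m2"], report.variances["after.footprint_m2"]],
           color=["#888", "#2a7"])
    ax.set_xticks([0, 1], ["before", "after"])
    ax.set_title("footprint variance (m$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
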