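"""Ground-truthed synthetic seafloor scenes.

Towed-camera seafloor photographs of nodule provinces share a handful of
degradations: a bright central light cone fading radially towards the
edges (artificial illumination), a blue-green color cast (water absorbs
red first), weak local contrast, an altitude-dependent scale (px/cm), and
three red laser dots projected onto the seabed at a calibrated separation
for scaling.  This module renders small scenes exhibiting all of them —
textured sediment, dark nodule-like ellipses, multiplicative radial
vignette, per-channel cast, Gaussian sensor noise, and laser dots at an
equilateral-triangle layout — together with the exact ground truth
(scale, dot positions, vignette and cast parameters, nodule centers), so
every pipeline stage is testable without any real data.

The renderer is fully deterministic: identical :class:`SceneParams`
(including the seed) produce a bit-identical raster.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian

from .errors import GeometryError
from .images import ImageRecord
from .metadata import MetadataRecord

#: Default first-frame timestamp for synthetic transects (UTC).
TRANSECT_EPOCH = dt.datetime(2019, 3, 4, 9, 35, 10)
#: Still-camera capture interval: one frame every 10 s (0.1 Hz).
CAPTURE_INTERVAL_S = 10


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one synthetic seafloor frame.

    The pixel scale follows the pinhole proportionality
    ``px_per_cm = base_scale_px_per_cm_at_1m / altitude_m``: flying twice as
    high halves the ground resolution.  Scene brightness falls off with
    altitude too (``background_mean`` is the sediment mean at 1 m, scaled
    by ``1/altitude``), and the blue-green cast deepens with the water
    path: ``color_cast`` holds per-meter transmission multipliers applied
    as ``cast ** altitude_m`` (Beer-Lambert), so frames from different
    altitudes differ in brightness *and* color balance — the degradations
    the color-normalization stage corrects.  Defaults render a 480x720
    (3:2) frame at 1.5 m altitude, i.e. 20 px/cm.
    """

    seed: int = 0
    width_px: int = 720
    height_px: int = 480
    altitude_m: float = 1.5
    base_scale_px_per_cm_at_1m: float = 30.0
    vignette_strength: float = 0.6
    vignette_radius_frac: float = 0.9
    color_cast: tuple[float, float, float] = (0.80, 0.90, 0.97)
    nodule_density_per_m2: float = 30.0
    nodule_radius_cm: tuple[float, float] = (0.8, 3.0)
    laser_separation_cm: float = 10.0
    laser_dot_radius_px: int = 3
    noise_sd: float = 4.0
    background_mean: float = 150.0  # sediment mean intensity at 1 m altitude

    @property
    def true_scale_px_per_cm(self) -> float:
        return self.base_scale_px_per_cm_at_1m / self.altitude_m


@dataclass
class GroundTruth:
    """Everything the renderer knows that the pipeline must recover."""

    true_scale_px_per_cm: float
    laser_points_px: np.ndarray  # (3, 2) float, (row, col)
    laser_separation_cm: float
    vignette_strength: float
    vignette_radius_frac: float
    color_cast: tuple[float, float, float]
    nodule_centers_px: list[tuple[float, float]] = field(default_factory=list)


def vignette_map(height_px: int, width_px: int, strength: float, radius_frac: float) -> np.ndarray:
    """Multiplicative radial falloff ``1 - strength * (1 - exp(-(r/R)^2))``.

    ``r`` is the distance from the image center and ``R`` is
    ``radius_frac`` times the half-diagonal, so the corners of a frame with
    ``radius_frac < 1`` sit beyond one falloff radius.  The map equals 1 at
    the center and decreases monotonically with ``r``.
    """
    rows = np.arange(height_px, dtype=float) - (height_px - 1) / 2.0
    cols = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    half_diag = 0.5 * np.hypot(height_px, width_px)
    big_r = radius_frac * half_diag
    return 1.0 - strength * (1.0 - np.exp(-r2 / big_r**2))


def laser_triangle_px(
    height_px: int, width_px: int, side_px: float
) -> np.ndarray:
    """Vertices of an equilateral triangle of the given side, centered mid-image.

    One vertex points up (towards row 0); returns a (3, 2) float array of
    (row, col) coordinates.
    """
    cy = (height_px - 1) / 2.0
    cx = (width_px - 1) / 2.0
    circumradius = side_px / np.sqrt(3.0)
    bearings = np.deg2rad([0.0, 120.0, 240.0])
    rows = cy - circumradius * np.cos(bearings)
    cols = cx + circumradius * np.sin(bearings)
    return np.column_stack([rows, cols])


def generate_scene(params: SceneParams) -> tuple[ImageRecord, GroundTruth]:
    """Render one scene and its ground truth.

    Raises
    ------
    GeometryError
        If the laser dots would fall outside the frame (separation too
        large for the scale/frame combination).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    scale = params.true_scale_px_per_cm

    # Illumination reaching the camera drops with altitude (spreading and
    # attenuation, partly compensated by exposure): ~1/altitude.
    illumination = 1.0 / params.altitude_m
    mean_intensity = params.background_mean * illumination

    # Textured sediment: smooth random field around the background mean.
    texture = rng.normal(0.0, 1.0, size=(h, w))
    texture = gaussian(texture, sigma=3.0, preserve_range=True)
    texture *= 12.0 * illumination / max(texture.std(), 1e-12)
    base = mean_intensity + texture

    # Dark nodule-like ellipses; expected count follows the physical area.
    area_m2 = (h / scale) * (w / scale) / 1e4
    n_nodules = int(rng.poisson(params.nodule_density_per_m2 * area_m2))
    nodule_centers: list[tuple[float, float]] = []
    darkness = np.ones((h, w))
    for _ in range(n_nodules):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius_cm = rng.uniform(*params.nodule_radius_cm)
        r_px = max(radius_cm * scale, 1.0)
        aspect = rng.uniform(0.7, 1.0)
        angle = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, r_px, r_px * aspect, shape=(h, w), rotation=angle)
        darkness[rr, cc] = rng.uniform(0.15, 0.35)
        nodule_centers.append((cy, cx))
    base = base * darkness

    vmap = vignette_map(h, w, params.vignette_strength, params.vignette_radius_frac)
    # Beer-Lambert: per-meter transmission multipliers, deepening with altitude.
    cast = np.asarray(params.color_cast, dtype=float) ** params.altitude_m
    raster = base[:, :, None] * vmap[:, :, None] * cast[None, None, :]
    if params.noise_sd > 0:
        raster = raster + rng.normal(0.0, params.noise_sd, size=(h, w, 3))
    raster = np.clip(np.round(raster), 0, 255).astype(np.uint8)

    # Laser dots go on top of everything (they outshine the scene).
    side_px = params.laser_separation_cm * scale
    points = laser_triangle_px(h, w, side_px)
    margin = params.laser_dot_radius_px
    if (
        points[:, 0].min() < margin
        or points[:, 0].max() >= h - margin
        or points[:, 1].min() < margin
        or points[:, 1].max() >= w - margin
    ):
        raise GeometryError(
            f"laser dots (triangle side {side_px:.0f} px) do not fit a {h}x{w} frame; "
            "use a smaller laser separation or a lower scale (higher altitude)"
        )
    for row, col in points:
        rr, cc = draw_disk((round(row), round(col)), params.laser_dot_radius_px, shape=(h, w))
        raster[rr, cc] = (255, 0, 0)

    truth = GroundTruth(
        true_scale_px_per_cm=scale,
        laser_points_px=points,
        laser_separation_cm=params.laser_separation_cm,
        vignette_strength=params.vignette_strength,
        vignette_radius_frac=params.vignette_radius_frac,
        color_cast=params.color_cast,
        nodule_centers_px=nodule_centers,
    )
    record = ImageRecord(pixels=raster)
    return record, truth


def generate_transect(
    n: int,
    seed: int = 0,
    altitude_range: tuple[float, float] = (1.0, 3.0),
    params: SceneParams | None = None,
    cruise: str = "SYN01",
    station: str = "100-1",
    platform: str = "OFOS",
    start_time: dt.datetime = TRANSECT_EPOCH,
) -> list[tuple[ImageRecord, GroundTruth]]:
    """Render a towed-camera transect of ``n`` frames.

    Altitude is drawn uniformly from ``altitude_range`` per frame (seeded),
    emulating a platform that cannot hold constant altitude; timestamps
    advance by 10 s per frame (0.1 Hz capture) and filenames follow the
    ``<cruise_station_platform_date_time.JPG>`` convention.
    """
    if n < 1:
        raise ValueError("a transect needs at least one frame")
    base = params if params is not None else SceneParams(seed=seed)
    rng = np.random.default_rng(seed)
    altitudes = rng.uniform(altitude_range[0], altitude_range[1], size=n)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)
    out: list[tuple[ImageRecord, GroundTruth]] = []
    for i in range(n):
        p = replace(base, altitude_m=float(altitudes[i]), seed=int(scene_seeds[i]))
        record, truth = generate_scene(p)
        ts = start_time + dt.timedelta(seconds=CAPTURE_INTERVAL_S * i)
        record.filename = f"{cruise}_{station}_{platform}_{ts:%Y%m%d}_{ts:%H%M%S}.JPG"
        record.acquisition_time = ts
        out.append((record, truth))
    return out


def transect_metadata(
    scenes: list[tuple[ImageRecord, GroundTruth]],
    contract_area: str = "German",
    depth_m: float = 4250.0,
    origin: tuple[float, float] = (12.6088, -119.9753),
    seed: int = 0,
) -> list[MetadataRecord]:
    """Synthesize a metadata row per frame, in the archive schema.

    Positions drift slowly from ``origin`` (a plausible nodule-province
    location) at towing speed; substrate classes and scores are random
    plausible values.  The archived cm/pixel scale is the ground truth's
    reciprocal, so metadata-based and laser-based scales agree exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, (record, truth) in enumerate(scenes):
        records.append(
            MetadataRecord(
                image_name=record.filename,
                contract_area=contract_area,
                depth_m=depth_m,
                latitude=origin[0] + 2.3e-5 * i,
                longitude=origin[1] + rng.normal(0, 2e-6),
                acquired_at=record.acquisition_time,
                original_scale_cm_per_px=1.0 / truth.true_scale_px_per_cm,
                seafloor_class=str(rng.choice(["A", "B", "C", "D"], p=[0.05, 0.5, 0.3, 0.15])),
                class_score=float(np.round(rng.uniform(0.5, 1.0), 6)),
                extras={},
            )
        )
    return records
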