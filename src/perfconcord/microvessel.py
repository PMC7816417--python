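"""Microvessel quantification in immunostain-like raster images.

Works on a single unit-normalized stain channel (the brown endothelial
stain after color unmixing).  Candidate vessels are stained rings around
an unstained lumen; isolated stain dots (mast cells, dendritic cells,
activated stroma) must not be counted.  Detection: binarize, close small
ring gaps, fill enclosed lumina, then keep connected components that pass
an area window and a ring criterion (fraction of the filled object that
was unstained lumen).  Metrics follow the standard histological
definitions: MVD is the vessel count per mm² of analyzed area and MVA is
the summed vessel area (lumen included) as a fraction of analyzed area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure, morphology

DEFAULT_STAIN_THRESHOLD = 0.5
DEFAULT_MIN_AREA_UM2 = 50.0
DEFAULT_MAX_AREA_UM2 = 50_000.0
DEFAULT_RING_CRITERION = 0.10


@dataclass
class VesselImage:
    """Single-channel stain raster with physical pixel size."""

    raster: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.raster.size and (self.raster.min() < 0 or self.raster.max() > 1):
            raise ValueError("stain intensities must lie in [0, 1]")

    @property
    def analyzed_area_mm2(self) -> float:
        return self.raster.size * (self.microns_per_pixel / 1000.0) ** 2


@dataclass
class VesselObject:
    """One detected vessel: filled area (lumen included) and location."""

    label: int
    area_mm2: float
    centroid_px: tuple[float, float]
    lumen_fraction: float


@dataclass
class VesselMetrics:
    MVD: float  # count / mm²
    MVA: float  # area fraction
    vessel_count: int
    total_vessel_area_mm2: float
    analyzed_area_mm2: float


def segment_vessels(
    image: VesselImage,
    stain_threshold: float = DEFAULT_STAIN_THRESHOLD,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    ring_criterion: float = DEFAULT_RING_CRITERION,
    closing_radius_um: float = 2.0,
) -> list[VesselObject]:
    """Detect ring-shaped vessel objects in the stain channel.

    A component is accepted if its filled area falls inside
    ``[min_area_um2, max_area_um2]`` and at least ``ring_criterion`` of
    the filled area is enclosed unstained lumen.  Dotted single-cell
    stains fail both the area window and the ring criterion.  Ring gaps
    up to ``closing_radius_um`` are closed before lumen filling; the
    closing footprint scales with the pixel pitch and is skipped when a
    single pixel already exceeds it (coarse rasters, where closing would
    obliterate small lumina).
    """
    if not 0 < stain_threshold < 1:
        raise ValueError("stain_threshold must lie in (0, 1)")
    if min_area_um2 >= max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    if image.raster.size == 0:
        return []

    mpp = image.microns_per_pixel
    px_area_um2 = mpp**2
    stained = image.raster >= stain_threshold
    close_px = int(round(closing_radius_um / mpp))
    if close_px >= 1:
        closed = morphology.closing(stained, morphology.disk(close_px))
    else:
        closed = stained
    filled = ndimage.binary_fill_holes(closed)
    labels = measure.label(filled, connectivity=2)

    objects: list[VesselObject] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area_um2
        if not min_area_um2 <= area_um2 <= max_area_um2:
            continue
        sl = region.slice
        mask = labels[sl] == region.label
        lumen_px = int((mask & ~closed[sl]).sum())
        lumen_frac = lumen_px / region.area
        if lumen_frac < ring_criterion:
            continue
        objects.append(
            VesselObject(
                label=region.label,
                area_mm2=area_um2 / 1e6,
                centroid_px=tuple(region.centroid),
                lumen_fraction=lumen_frac,
            )
        )
    return objects


def compute_metrics(objects: list[VesselObject], image: VesselImage) -> VesselMetrics:
    """MVD (count/mm²) and MVA (area fraction, lumen included)."""
    area = image.analyzed_area_mm2
    total = sum(o.area_mm2 for o in objects)
    return VesselMetrics(
        MVD=len(objects) / area,
        MVA=total / area,
        vessel_count=len(objects),
        total_vessel_area_mm2=total,
        analyzed_area_mm2=area,
    )


# ---------------------------------------------------------------- file I/O

def save_vessel_image(image: VesselImage, path) -> None:
    """Write the raster as 8-bit TIFF plus a JSON sidecar with pixel size."""
    path = Path(path)
    tifffile.imwrite(path, (image.raster * 255).astype(np.uint8))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"microns_per_pixel": image.microns_per_pixel})
    )


def load_vessel_image(path, microns_per_pixel: float | None = None) -> VesselImage:
    """Read TIFF/PNG; pixel pitch from the JSON sidecar unless given."""
    path = Path(path)
    raster = tifffile.imread(path).astype(float)
    if raster.max() > 1:
        raster = raster / 255.0
    if microns_per_pixel is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no pixel-size sidecar for {path}; pass microns_per_pixel"
            )
        microns_per_pixel = json.loads(sidecar.read_text())["microns_per_pixel"]
    return VesselImage(raster=np.clip(raster, 0, 1),
                       microns_per_pixel=float(microns_per_pixel))


def metrics_to_frame(rows: list[tuple[str, VesselMetrics]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [sid for sid, _ in rows],
            "mvd_per_mm2": [m.MVD for _, m in rows],
            "mva_fraction": [m.MVA for _, m in rows],
            "vessel_count": [m.vessel_count for _, m in rows],
            "analyzed_area_mm2": [m.analyzed_area_mm2 for _, m in rows],
        }
    )
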