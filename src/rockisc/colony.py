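"""Colony-forming-efficiency quantification from stained plate scans.

The segmentation pipeline mirrors a standard grayscale colony count: median
filter (radius 2 px), global intermeans ("IsoData") threshold selecting the
dark foreground, binary hole filling, and a distance-transform watershed to
separate touching colonies.  Measurements are calibrated by the scan DPI
(pixels per mm = dpi / 25.4).  Colonies of at least 1 mm^2 with circularity
4*pi*A/P^2 of at least 0.5 are counted; perimeters use the Crofton
estimator, which is far less biased than pixel-edge counting, and
circularities marginally above 1 from digitization are clamped to 1 for
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

MM_PER_INCH = 25.4


class ColonyError(ValueError):
    pass


@dataclass
class PlateImage:
    pixels: np.ndarray     # 2-D uint8 grayscale
    dpi: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ColonyError("plate image must be 2-D grayscale")
        if self.dpi <= 0:
            raise ColonyError("dpi must be > 0")

    @property
    def px_per_mm(self) -> float:
        return self.dpi / MM_PER_INCH


def segment_colonies(img: PlateImage, threshold: str = "isodata",
                     min_separation_mm: float = 0.5) -> np.ndarray:
    """Labeled colony mask (0 = background)."""
    pixels = img.pixels
    smoothed = median_filter(pixels, footprint=disk(2))
    if smoothed.min() == smoothed.max():
        return np.zeros_like(pixels, dtype=np.int32)
    thresh_fn = {"isodata": threshold_isodata, "otsu": threshold_otsu}[threshold]
    t = thresh_fn(smoothed)
    mask = smoothed < t  # colonies are dark on a light background
    if not mask.any() or mask.all():
        return np.zeros_like(pixels, dtype=np.int32)
    # a threshold on pure background noise splits the noise in half; demand
    # real stain contrast between the two classes before calling colonies
    contrast = float(smoothed[~mask].mean()) - float(smoothed[mask].mean())
    if contrast < 25.0:
        return np.zeros_like(pixels, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    distance = ndi.gaussian_filter(distance, sigma=2.0)
    min_dist = max(3, int(round(min_separation_mm * img.px_per_mm)))
    coords = peak_local_max(distance, min_distance=min_dist, labels=mask)
    if len(coords) == 0:
        return cc_label(mask).astype(np.int32)
    peaks = np.zeros_like(mask, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, _ = ndi.label(peaks)
    return watershed(-distance, markers, mask=mask).astype(np.int32)


def measure_colonies(labels: np.ndarray, dpi: float) -> pd.DataFrame:
    """Per-colony area (mm^2), perimeter (mm), circularity and centroid."""
    if dpi <= 0:
        raise ColonyError("dpi must be > 0")
    px_per_mm = dpi / MM_PER_INCH
    rows = []
    for rp in regionprops(labels):
        area_mm2 = rp.area / px_per_mm ** 2
        perim_px = rp.perimeter_crofton
        perim_mm = perim_px / px_per_mm
        circ = 4.0 * np.pi * rp.area / perim_px ** 2 if perim_px > 0 else 0.0
        rows.append({
            "label": rp.label,
            "area_mm2": float(area_mm2),
            "perimeter_mm": float(perim_mm),
            "circularity": float(circ),
            "centroid_y": float(rp.centroid[0]),
            "centroid_x": float(rp.centroid[1]),
        })
    table = pd.DataFrame(rows, columns=["label", "area_mm2", "perimeter_mm",
                                        "circularity", "centroid_y", "centroid_x"])
    return table


def filter_colonies(table: pd.DataFrame, min_area_mm2: float = 1.0,
                    min_circularity: float = 0.5) -> pd.DataFrame:
    """Flag colonies passing the >= area and >= circularity rules."""
    out = table.copy()
    circ = np.minimum(out["circularity"].to_numpy() if len(out) else np.array([]), 1.0)
    if len(out):
        out["passes_filter"] = (out["area_mm2"].to_numpy() >= min_area_mm2) & \
            (circ >= min_circularity)
    else:
        out["passes_filter"] = pd.Series([], dtype=bool)
    return out


def count_colonies(img: PlateImage, min_area_mm2: float = 1.0,
                   min_circularity: float = 0.5,
                   threshold: str = "isodata") -> tuple[int, pd.DataFrame]:
    """Segment, measure and filter in one call; returns (count, table)."""
    labels = segment_colonies(img, threshold=threshold)
    table = filter_colonies(measure_colonies(labels, img.dpi),
                            min_area_mm2, min_circularity)
    n = int(table["passes_filter"].sum()) if len(table) else 0
    return n, table


@dataclass
class GrowthRecord:
    n_seeded: float
    n_harvested: float
    duration_days: float

    def __post_init__(self):
        if self.n_seeded <= 0 or self.n_harvested <= 0 or self.duration_days <= 0:
            raise ColonyError("growth record entries must be positive")


def growth_rate(record: GrowthRecord) -> float:
    """ln(harvested / seeded) / duration, in per-day units."""
    return float(np.log(record.n_harvested / record.n_seeded) / record.duration_days)


@dataclass
class CFEResult:
    colonies_counted: int
    cells_seeded: int
    cfe_percent: float


def cfe(colonies_counted: int, cells_seeded: int = 800) -> CFEResult:
    """Colony-forming efficiency as percent of seeded cells forming colonies."""
    if cells_seeded <= 0:
        raise ColonyError("cells_seeded must be > 0")
    return CFEResult(colonies_counted=int(colonies_counted),
                     cells_seeded=int(cells_seeded),
                     cfe_percent=100.0 * colonies_counted / cells_seeded)
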