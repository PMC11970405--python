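"""Cluster segmentation and area measurement in well micrographs.

A drug-test well is photographed at baseline (t0) and endpoint (t1).  This
module turns each grayscale image into a per-well total cluster area in
physical units: global Otsu thresholding (with automatic polarity
detection, clusters being the minority phase), hole filling, morphological
opening, connected-component labeling, then per-region area and
equivalent diameter.  Clusters with equivalent diameter not exceeding
40 um are discarded before summing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening

__all__ = [
    "WellImage",
    "SegmentationConfig",
    "ClusterMeasurement",
    "WellAreaSummary",
    "segment_clusters",
    "measure_clusters",
    "filter_by_diameter",
    "total_area",
    "measure_well",
]

DEFAULT_MIN_DIAMETER_UM = 40.0


@dataclass(frozen=True)
class WellImage:
    """One grayscale micrograph of a well at one timepoint."""

    pixels: np.ndarray
    pixel_size_um: float
    well_id: str = ""
    timepoint: str = "t0"

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if np.asarray(self.pixels).size == 0:
            raise ValueError("image grid must be non-empty")


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the default segmentation.

    polarity: "dark" treats below-threshold pixels as clusters (brightfield
    default), "bright" the opposite, "auto" picks the minority phase.
    opening_radius_px must stay smaller than the smallest cluster of
    interest (radius 3 px removes specks well under the 40 um filter at
    typical 1-2 um/px scales).
    """

    polarity: Literal["auto", "dark", "bright"] = "auto"
    opening_radius_px: int = 3
    fill_holes: bool = True


@dataclass(frozen=True)
class ClusterMeasurement:
    """Area and equivalent diameter of one segmented cluster.

    equivalent_diameter is the diameter of the circle with the same area,
    2*sqrt(area/pi); clusters are near-spherical so this operationalizes
    "diameter".
    """

    label: int
    area_um2: float
    equivalent_diameter_um: float
    centroid_px: tuple[float, float]
    well_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("area must be > 0")


@dataclass(frozen=True)
class WellAreaSummary:
    """Total retained cluster area S of one well at one timepoint."""

    well_id: str
    timepoint: str
    n_clusters_retained: int
    total_area_um2: float


def segment_clusters(image: WellImage | np.ndarray,
                     config: SegmentationConfig | None = None) -> np.ndarray:
    """Label map of clusters; background is 0, clusters are 1..N.

    Constant images yield zero regions (an empty well, not an error);
    NaN pixels are rejected.
    """
    config = config or SegmentationConfig()
    pixels = image.pixels if isinstance(image, WellImage) else np.asarray(image)
    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    if pixels.max() == pixels.min():
        return np.zeros(pixels.shape, dtype=np.int32)

    thresh = threshold_otsu(pixels)
    dark = pixels < thresh
    if config.polarity == "dark":
        mask = dark
    elif config.polarity == "bright":
        mask = ~dark
    else:  # minority phase is the foreground
        mask = dark if dark.mean() <= 0.5 else ~dark

    if config.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if config.opening_radius_px > 0:
        mask = opening(mask, disk(config.opening_radius_px))
    return sk_label(mask, connectivity=2).astype(np.int32)


def measure_clusters(labels: np.ndarray, pixel_size_um: float,
                     well_id: str = "", timepoint: str = "") -> list[ClusterMeasurement]:
    """Per-cluster area (pixel count x pixel_size^2) and equivalent diameter."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    out = []
    for region in regionprops(labels):
        area = float(region.area) * pixel_size_um**2
        out.append(ClusterMeasurement(
            label=int(region.label),
            area_um2=area,
            equivalent_diameter_um=2.0 * float(np.sqrt(area / np.pi)),
            centroid_px=tuple(float(c) for c in region.centroid),
            well_id=well_id,
            timepoint=timepoint,
        ))
    return out


def filter_by_diameter(measurements: Sequence[ClusterMeasurement],
                       min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
                       inclusive: bool = False) -> list[ClusterMeasurement]:
    """Keep clusters whose equivalent diameter exceeds ``min_diameter_um``.

    The boundary is exclusive by default ("exceeding 40 um"); pass
    ``inclusive=True`` for a >= comparison in sensitivity analyses.
    Input order is preserved.
    """
    if min_diameter_um < 0:
        raise ValueError("min_diameter_um must be >= 0")
    if inclusive:
        return [m for m in measurements if m.equivalent_diameter_um >= min_diameter_um]
    return [m for m in measurements if m.equivalent_diameter_um > min_diameter_um]


def total_area(retained: Sequence[ClusterMeasurement],
               well_id: str | None = None,
               timepoint: str | None = None) -> WellAreaSummary:
    """Sum retained cluster areas into the well-level S used for viability.

    All measurements must come from one (well, timepoint); mixed tags are
    rejected.  An empty list is a valid empty well (S = 0).
    """
    wells = {m.well_id for m in retained if m.well_id}
    tps = {m.timepoint for m in retained if m.timepoint}
    if len(wells) > 1 or len(tps) > 1:
        raise ValueError(f"measurements span multiple wells/timepoints: {wells or tps}")
    return WellAreaSummary(
        well_id=well_id if well_id is not None else (next(iter(wells)) if wells else ""),
        timepoint=timepoint if timepoint is not None else (next(iter(tps)) if tps else ""),
        n_clusters_retained=len(retained),
        total_area_um2=float(sum(m.area_um2 for m in retained)),
    )


def measure_well(image: WellImage,
                 min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
                 config: SegmentationConfig | None = None) -> WellAreaSummary:
    """segment -> measure -> filter(> min diameter) -> sum, in one call."""
    labels = segment_clusters(image, config)
    measurements = measure_clusters(labels, image.pixel_size_um,
                                    well_id=image.well_id,
                                    timepoint=image.timepoint)
    retained = filter_by_diameter(measurements, min_diameter_um)
    return total_area(retained, well_id=image.well_id, timepoint=image.timepoint)
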