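"""Label segmentation and per-component size/intensity measurement.

AI triage heatmaps arrive as 8-bit RGB overlays in which suspected-lesion
labels are drawn in hot colors. Positive label pixels are segmented by
thresholding the blue channel (a value of 100 is the maximum admissible
blue for a label pixel), grouped into connected components, and summarized
by two scalars:

* size — number of positive pixels times the pixel size. The default
  convention squares the pixel size (an in-plane area in mm²); the literal
  linear product is selectable because both readings of "multiplied by the
  pixel size" occur in practice.
* intensity — label RGB values converted to grayscale, inverted and
  normalized to [0, 1], then averaged over the component's pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .design import AcquisitionCondition
from .errors import FormatError, ValidationError

DEFAULT_BLUE_THRESHOLD = 100

#: ITU-R BT.601 luma weights (R, G, B); the common RGB->gray convention.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

CONNECTIVITIES = ("plane4", "plane8", "volume26")

SIZE_CONVENTIONS = ("area", "linear")


@dataclass
class HeatmapSeries:
    """An 8-bit RGB overlay stack tied to one acquisition.

    ``pixels`` has shape (slice, row, col, 3) and dtype uint8.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    slice_thickness_mm: float
    acquisition: AcquisitionCondition | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise FormatError(
                f"expected (slice, row, col, 3) RGB stack, got shape "
                f"{self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValidationError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape[:3]


@dataclass
class LabelComponent:
    """One maximal connected region of positive label pixels."""

    component_id: int
    pixel_coords: np.ndarray  # (n, 3) int array of (slice, row, col)
    size: float | None = None
    intensity: float | None = None

    def __post_init__(self):
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.intp)
        if self.pixel_coords.ndim != 2 or self.pixel_coords.shape[1] != 3:
            raise ValidationError("pixel_coords must be an (n, 3) array")
        if len(self.pixel_coords) == 0:
            raise ValidationError("components must be non-empty")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)

    @property
    def centroid_voxel(self) -> np.ndarray:
        return self.pixel_coords.mean(axis=0)

    def centroid_mm(
        self, pixel_size_mm: float, slice_thickness_mm: float
    ) -> np.ndarray:
        scale = np.array([slice_thickness_mm, pixel_size_mm, pixel_size_mm])
        return self.centroid_voxel * scale


def segment_label_mask(
    series: HeatmapSeries | np.ndarray,
    blue_threshold: int = DEFAULT_BLUE_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of positive label pixels: blue(p) <= blue_threshold.

    The threshold is inclusive ("maximum" admissible blue value) and
    defaults to 100 on the 8-bit scale.
    """
    if not 0 <= blue_threshold <= 255:
        raise ValidationError("blue_threshold must be in [0, 255]")
    pixels = series.pixels if isinstance(series, HeatmapSeries) else np.asarray(series)
    if pixels.ndim != 4 or pixels.shape[-1] != 3:
        raise FormatError("segmentation requires an RGB (slice,row,col,3) stack")
    return pixels[..., 2] <= blue_threshold


def extract_components(
    mask: np.ndarray, connectivity: str = "volume26"
) -> list[LabelComponent]:
    """Group mask-true pixels into maximal connected components.

    ``volume26`` (default) connects across slices so a label spanning
    slices is one component; ``plane4``/``plane8`` group each slice
    independently. Components are ordered by (min slice, min row, min col)
    of their pixels and numbered from 0 in that order.
    """
    if connectivity not in CONNECTIVITIES:
        raise ValidationError(
            f"connectivity must be one of {CONNECTIVITIES}, got {connectivity!r}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise FormatError("mask must be a 3-D (slice, row, col) array")

    if connectivity == "volume26":
        labeled = measure.label(mask, connectivity=3)
    else:
        conn = 1 if connectivity == "plane4" else 2
        labeled = np.zeros(mask.shape, dtype=np.int64)
        offset = 0
        for s in range(mask.shape[0]):
            sl = measure.label(mask[s], connectivity=conn)
            sl[sl > 0] += offset
            labeled[s] = sl
            offset = labeled[s].max()

    comps = []
    for lab in range(1, int(labeled.max()) + 1):
        coords = np.argwhere(labeled == lab)
        if len(coords):
            comps.append(coords)
    comps.sort(key=lambda c: tuple(c.min(axis=0)))
    return [
        LabelComponent(component_id=i, pixel_coords=c) for i, c in enumerate(comps)
    ]


def component_size(
    component: LabelComponent,
    pixel_size_mm: float,
    convention: str = "area",
) -> float:
    """Label size: positive-pixel count times the pixel size.

    ``area`` (default): n x pixel_size² in mm². ``linear``: the literal
    product n x pixel_size.
    """
    if pixel_size_mm <= 0:
        raise ValidationError("pixel_size_mm must be > 0")
    if convention not in SIZE_CONVENTIONS:
        raise ValidationError(f"unknown size convention {convention!r}")
    n = component.n_pixels
    if convention == "area":
        return n * pixel_size_mm**2
    return n * pixel_size_mm


def component_intensity(
    component: LabelComponent,
    series: HeatmapSeries | np.ndarray,
    luma: str = "bt601",
) -> float:
    """Mean inverted normalized grayscale over the component's pixels.

    Each pixel contributes (255 - gray) / 255 with gray computed in
    floating point from the configured luma transform, so the result lies
    in [0, 1] (1 = black label on the 8-bit scale).
    """
    pixels = series.pixels if isinstance(series, HeatmapSeries) else np.asarray(series)
    if luma == "bt601":
        weights = np.array(BT601_WEIGHTS)
    elif luma == "mean":
        weights = np.full(3, 1.0 / 3.0)
    else:
        raise ValidationError(f"unknown luma transform {luma!r}")
    coords = component.pixel_coords
    rgb = pixels[coords[:, 0], coords[:, 1], coords[:, 2]].astype(float)
    gray = rgb @ weights
    return float(np.mean((255.0 - gray) / 255.0))


def quantify_series(
    series: HeatmapSeries,
    blue_threshold: int = DEFAULT_BLUE_THRESHOLD,
    connectivity: str = "volume26",
    luma: str = "bt601",
) -> pd.DataFrame:
    """Segment one heatmap series and measure every component.

    Returns a tidy frame with one row per component: pixel count, size
    under both conventions, intensity, and centroids in voxel and mm
    coordinates.
    """
    mask = segment_label_mask(series, blue_threshold)
    comps = extract_components(mask, connectivity)
    return measure_components(series, comps, luma)


def measure_components(
    series: HeatmapSeries,
    comps: list[LabelComponent],
    luma: str = "bt601",
) -> pd.DataFrame:
    """Measure already-extracted components against their series."""
    rows = []
    scan_id = series.acquisition.scan_id if series.acquisition else None
    for comp in comps:
        comp.size = component_size(comp, series.pixel_size_mm, "area")
        comp.intensity = component_intensity(comp, series, luma)
        cv = comp.centroid_voxel
        cm = comp.centroid_mm(series.pixel_size_mm, series.slice_thickness_mm)
        rows.append(
            {
                "scan_id": scan_id,
                "component_id": comp.component_id,
                "n_pixels": comp.n_pixels,
                "size_mm2": comp.size,
                "size_linear": component_size(comp, series.pixel_size_mm, "linear"),
                "intensity": comp.intensity,
                "centroid_slice": cv[0],
                "centroid_row": cv[1],
                "centroid_col": cv[2],
                "centroid_z_mm": cm[0],
                "centroid_y_mm": cm[1],
                "centroid_x_mm": cm[2],
            }
        )
    columns = [
        "scan_id", "component_id", "n_pixels", "size_mm2", "size_linear",
        "intensity", "centroid_slice", "centroid_row", "centroid_col",
        "centroid_z_mm", "centroid_y_mm", "centroid_x_mm",
    ]
    return pd.DataFrame(rows, columns=columns)
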