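"""DAB-positive area measurement and conversion to TIL densities.

Brightfield immunohistochemistry with a DAB chromogen (brown, marking
CD3+/CD8+ cells) over a hematoxylin counterstain obeys the Beer-Lambert
law: stain amounts add linearly in optical density (OD) space. The pipeline
is

1. convert RGB to OD,
2. unmix OD into hematoxylin and DAB channels against known stain vectors,
3. threshold the DAB channel to a positive-pixel mask,
4. remove out-of-size connected components (speckle, smears) and manually
   excluded areas,
5. convert positive area inside a region of interest to a cell count via
   the mean lymphocyte area (60 um**2) and to a density in cells/mm**2.

The cell count is a continuous area ratio — it is deliberately not rounded;
rounding happens only in report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import DataError, ParameterError, ZeroAreaError
from .roigeom import RegionAnnotation, rasterize_region, region_area_mm2

#: Ruifrok-Johansson H-DAB optical-density vectors (literature standard).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.269, 0.568, 0.778)

#: Mean lymphocyte area used to convert positive area to a cell count.
LYMPHOCYTE_AREA_UM2 = 60.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("stain vector must be non-zero")
    return v / n


@dataclass
class StainConfig:
    """Tunables of the positive-area measurement.

    Attributes
    ----------
    hematoxylin_od_vector, dab_od_vector : 3-vectors
        Unit OD absorption directions of the two stains (defaults:
        Ruifrok-Johansson H-DAB values). Must be linearly independent.
    dab_threshold_od : float
        DAB-channel OD at or above which a pixel is called positive
        (inclusive). Default 0.15: separates chromogen from counterstain
        bleed-through in the package's forward model.
    min_object_area_um2, max_object_area_um2 : float
        Size window for plausible cell objects; connected components
        outside it are removed as speckle / smears (default 10-1000 um**2).
    lymphocyte_area_um2 : float
        Mean area of one lymphocyte; positive area / this = cell count.
    """

    hematoxylin_od_vector: tuple = HEMATOXYLIN_OD
    dab_od_vector: tuple = DAB_OD
    dab_threshold_od: float = 0.15
    min_object_area_um2: float = 10.0
    max_object_area_um2: float = 1000.0
    lymphocyte_area_um2: float = LYMPHOCYTE_AREA_UM2

    def __post_init__(self):
        self.hematoxylin_od_vector = tuple(_unit(self.hematoxylin_od_vector))
        self.dab_od_vector = tuple(_unit(self.dab_od_vector))
        if self.dab_threshold_od <= 0:
            raise ParameterError("dab_threshold_od must be > 0")
        if self.min_object_area_um2 < 0:
            raise ParameterError("min_object_area_um2 must be >= 0")
        if self.max_object_area_um2 <= self.min_object_area_um2:
            raise ParameterError("max_object_area_um2 must exceed min_object_area_um2")
        if self.lymphocyte_area_um2 <= 0:
            raise ParameterError("lymphocyte_area_um2 must be > 0")

    @property
    def stain_matrix(self) -> np.ndarray:
        """3x2 matrix with the hematoxylin and DAB OD vectors as columns."""
        m = np.column_stack([self.hematoxylin_od_vector, self.dab_od_vector])
        if np.linalg.cond(m) > 1e3:
            raise ParameterError("stain vectors are near-parallel (condition number > 1e3)")
        return m


@dataclass
class DensityRecord:
    """One density measurement: patient x marker x region.

    density_cells_per_mm2 = (positive_area_um2 / lymphocyte_area_um2)
    / region_area_mm2, with the cell count kept at full precision.
    """

    patient_id: str
    marker: str
    region: str
    positive_area_um2: float
    cell_count: float
    region_area_mm2: float
    density_cells_per_mm2: float = field(default=None)

    def __post_init__(self):
        if self.region_area_mm2 <= 0:
            raise ZeroAreaError("region_area_mm2 must be > 0")
        if self.density_cells_per_mm2 is None:
            self.density_cells_per_mm2 = self.cell_count / self.region_area_mm2


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density per channel: ``OD = -log10((I + 1) / 255)``.

    The +1 offset avoids log(0) at fully absorbed pixels; the blank-field
    intensity is fixed at 255 (no per-slide calibration). White maps to
    ~0 OD, full absorption to -log10(1/255) ~ 2.4 per channel.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise DataError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    if img.dtype != np.uint8:
        raise DataError(f"expected 8-bit RGB, got dtype {img.dtype}")
    return -np.log10((img.astype(float) + 1.0) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` up to 8-bit quantization."""
    intensity = 255.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve_hdab(od_image: np.ndarray, config: StainConfig | None = None):
    """Unmix an OD image into (hematoxylin, dab) concentration channels.

    Each pixel's OD vector is projected onto the two stain vectors by least
    squares; negative concentrations (noise) are clipped at zero.

    Returns
    -------
    (hematoxylin, dab) : pair of 2-D float arrays
    """
    config = config or StainConfig()
    m = config.stain_matrix  # may raise ParameterError on near-parallel vectors
    od = np.asarray(od_image, dtype=float)
    h, w = od.shape[:2]
    flat = od.reshape(-1, 3).T  # 3 x N
    conc, *_ = np.linalg.lstsq(m, flat, rcond=None)  # 2 x N
    conc = np.clip(conc, 0.0, None)
    return conc[0].reshape(h, w), conc[1].reshape(h, w)


def dab_positive_mask(dab_channel: np.ndarray, config: StainConfig | None = None) -> np.ndarray:
    """Pixels with DAB OD at or above the threshold (inclusive >=)."""
    config = config or StainConfig()
    return np.asarray(dab_channel) >= config.dab_threshold_od


def filter_artifacts(
    mask: np.ndarray,
    config: StainConfig,
    um_per_px: float,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Remove out-of-size connected components and excluded pixels.

    Components are 8-connected; a component is kept iff its area in um**2
    lies in [min_object_area_um2, max_object_area_um2]. ``exclude_mask``
    models areas a pathologist marked for manual removal.
    """
    if um_per_px <= 0:
        raise ParameterError("um_per_px must be > 0")
    px_area = um_per_px**2
    min_px = config.min_object_area_um2 / px_area
    max_px = config.max_object_area_um2 / px_area
    work = np.asarray(mask, dtype=bool).copy()
    if exclude_mask is not None:
        work &= ~np.asarray(exclude_mask, dtype=bool)
    labels = measure.label(work, connectivity=2)
    if labels.max() == 0:
        return work
    counts = np.bincount(labels.ravel())
    bad = (counts < min_px) | (counts > max_px)
    bad[0] = False
    if bad.any():
        work[bad[labels]] = False
    return work


def quantify_region(
    image: np.ndarray,
    annotation: RegionAnnotation,
    label: str,
    marker: str,
    config: StainConfig | None = None,
    patient_id: str = "",
) -> DensityRecord:
    """Full measurement for one region: positive area -> count -> density.

    Runs OD conversion, H-DAB unmixing, thresholding and size filtering,
    intersects the positive mask with the region mask, and converts the
    positive area to a cell count via the mean lymphocyte area and to a
    density over the region area in mm**2.
    """
    config = config or StainConfig()
    um_per_px = annotation.um_per_px
    region_mask = rasterize_region(annotation, label, image.shape[:2])
    area_mm2 = region_area_mm2(region_mask, um_per_px)  # raises on empty region

    od = rgb_to_od(image)
    _, dab = deconvolve_hdab(od, config)
    pos = dab_positive_mask(dab, config)
    exclude = None
    if "EXCLUDE" in annotation.labels():
        exclude = rasterize_region(annotation, "EXCLUDE", image.shape[:2])
    pos = filter_artifacts(pos, config, um_per_px, exclude_mask=exclude)

    positive_px = int(np.count_nonzero(pos & region_mask))
    positive_area_um2 = positive_px * um_per_px**2
    cell_count = positive_area_um2 / config.lymphocyte_area_um2
    return DensityRecord(
        patient_id=patient_id or annotation.slide_id,
        marker=marker,
        region=label,
        positive_area_um2=positive_area_um2,
        cell_count=cell_count,
        region_area_mm2=area_mm2,
    )


def qc_overlay(image: np.ndarray, positive_mask: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    """RGB overlay for visual QC: positive objects green, region outline blue."""
    from skimage.segmentation import find_boundaries

    out = image.copy()
    out[positive_mask] = (0, 180, 0)
    out[find_boundaries(region_mask, mode="outer")] = (0, 0, 255)
    return out
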