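"""Synthetic IHC slides and synthetic cohorts with known ground truth.

Two generators make the whole template testable end to end without any
scanned slide:

* :func:`render_slide` draws an H-DAB brightfield scene — white background,
  hematoxylin-toned background nuclei, DAB-toned (brown) lymphocytes placed
  at target densities inside the tumor-center and invasive-margin polygons —
  using the forward Beer-Lambert model (stain amounts add in OD space), so
  color deconvolution is exactly invertible in the noiseless case and the
  recorded :class:`GroundTruth` is an analytic oracle for the measurement
  pipeline.
* :func:`generate_cohort` draws per-patient marker densities from
  log-normal distributions (heavily right-skewed, as TIL densities are)
  whose defaults reproduce the quartile structure of a 119-patient colon
  cancer cohort: invasive-margin densities roughly double the tumor-center
  ones, and microsatellite-instable (MSI) tumors shifted upward for
  CD3_IM, CD8_TC and CD8_IM.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .errors import CapacityError, GeometryError, ParameterError, PlacementError
from .roigeom import as_polygon, rasterize_region, region_area_mm2, RegionAnnotation
from .stainquant import DAB_OD, HEMATOXYLIN_OD, od_to_rgb

MARKER_COLUMNS = ("CD3_TC", "CD3_IM", "CD8_TC", "CD8_IM")

#: Markers whose density is elevated in MSI tumors (CD3_TC shows no shift).
MSI_AFFECTED = ("CD3_IM", "CD8_TC", "CD8_IM")

#: Per-marker (median cells/mm**2, log-scale sigma). Medians equal the
#: cohort medians 393/858/220/513; sigma chosen so the inter-quartile
#: ratio of the log-normal matches the reported 25th/75th percentiles
#: (sigma = ln(p75/p25) / (2 * 0.6745)).
DEFAULT_MARKER_PARAMS = {
    "CD3_TC": (393.0, 1.039),
    "CD3_IM": (858.0, 0.833),
    "CD8_TC": (220.0, 1.057),
    "CD8_IM": (513.0, 0.870),
}

DEFAULT_STAGE_PROBABILITIES = (37 / 119, 43 / 119, 39 / 119)

#: OD amplitude of one rendered object along its stain vector.
DAB_AMPLITUDE = 1.0
HEMATOXYLIN_AMPLITUDE = 0.6


# ---------------------------------------------------------------------------
# Slide rendering
# ---------------------------------------------------------------------------

@dataclass
class SlideSpec:
    """Recipe for one synthetic slide.

    Densities are in cells/mm**2; ``cell_area_mean_um2`` defaults to the
    60 um**2 mean lymphocyte area that the measurement stage divides by.
    ``overlap`` switches off the minimum-center-distance constraint, which
    deliberately makes area-based counting undercount (merged blobs).
    """

    width_px: int
    height_px: int
    um_per_px: float
    tc_polygon: object
    im_polygon: object
    target_density_tc: float = 500.0
    target_density_im: float = 1000.0
    cell_area_mean_um2: float = 60.0
    cell_area_cv: float = 0.2
    background_nuclei_density: float = 500.0
    artifact_count: int = 0
    noise_sigma: float = 3.0 / 255.0
    overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("width_px", "height_px", "um_per_px", "cell_area_mean_um2"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "target_density_tc",
            "target_density_im",
            "cell_area_cv",
            "background_nuclei_density",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.artifact_count < 0:
            raise ParameterError("artifact_count must be >= 0")
        self.tc_polygon = as_polygon(self.tc_polygon)
        self.im_polygon = as_polygon(self.im_polygon)
        frame = sgeom.box(-0.5, -0.5, self.width_px - 0.5, self.height_px - 0.5)
        for label, poly in (("tc_polygon", self.tc_polygon), ("im_polygon", self.im_polygon)):
            if not frame.covers(poly):
                raise GeometryError(f"{label} does not fit inside the image frame")
        if self.tc_polygon.intersects(self.im_polygon) and not self.tc_polygon.touches(self.im_polygon):
            raise GeometryError("tc_polygon and im_polygon must be disjoint")

    def annotation(self, slide_id: str = "synthetic") -> RegionAnnotation:
        return RegionAnnotation(
            slide_id=slide_id,
            regions=[("TC", self.tc_polygon), ("IM", self.im_polygon)],
            um_per_px=self.um_per_px,
        )


@dataclass
class CellRecord:
    center_x: float
    center_y: float
    area_um2: float


@dataclass
class RegionTruth:
    """Exact bookkeeping of what was placed in one region."""

    label: str
    true_cell_count: int
    true_positive_area_um2: float
    region_area_mm2: float
    true_density: float
    cells: list = field(default_factory=list)


@dataclass
class GroundTruth:
    """Per-region truth plus the artifact log for one rendered slide.

    ``true_positive_area_um2`` is the area of the realized DAB footprint
    (union of painted pixels), i.e. the sum of per-cell areas minus any
    overlap, measured on the rendering grid.
    """

    regions: dict
    artifacts: list = field(default_factory=list)
    um_per_px: float = 1.0

    def total_cells(self) -> int:
        return sum(r.true_cell_count for r in self.regions.values())

    def to_dict(self) -> dict:
        return {
            "um_per_px": self.um_per_px,
            "regions": {k: asdict(v) for k, v in self.regions.items()},
            "artifacts": list(self.artifacts),
        }


def _sample_areas(rng, n, mean_um2, cv):
    """Log-normal cell areas with the requested mean and CV (exact at cv=0)."""
    if cv == 0:
        return np.full(n, mean_um2, dtype=float)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean_um2) - sigma2 / 2.0
    return np.exp(rng.normal(mu, math.sqrt(sigma2), size=n))


def _place_centers(rng, polygon, n, min_dist_px, max_batches=400):
    """Uniform centers in a polygon, optionally with a hard-core distance.

    Rejection sampling from the bounding box; with ``min_dist_px > 0`` a
    candidate is accepted only if no accepted center lies closer.
    Raises :class:`CapacityError` when placement stalls (density too high
    for the hard-core packing).
    """
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = polygon.bounds
    pts = np.empty((n, 2))
    k = 0
    stalled = 0
    batch = max(4 * n, 256)
    for _ in range(max_batches):
        xs = rng.uniform(minx, maxx, size=batch)
        ys = rng.uniform(miny, maxy, size=batch)
        ok = shapely.contains_xy(polygon, xs, ys)
        k_before = k
        for x, y in zip(xs[ok], ys[ok]):
            if min_dist_px > 0 and k:
                d2 = (pts[:k, 0] - x) ** 2 + (pts[:k, 1] - y) ** 2
                if d2.min() < min_dist_px**2:
                    continue
            pts[k] = (x, y)
            k += 1
            if k == n:
                return pts
        stalled = stalled + 1 if k == k_before else 0
        if stalled >= 10:  # saturated packing; give up early
            break
    raise CapacityError(
        f"could not place {n} cells with min distance {min_dist_px:.1f} px "
        f"in polygon of area {polygon.area:.0f} px^2"
    )


def _paint(od_image, rng, centers, areas_um2, um_per_px, vector, amplitude):
    """Add ``amplitude * vector`` OD over the ellipse footprint of each cell.

    Returns the boolean union footprint of all painted ellipses.
    """
    h, w = od_image.shape[:2]
    footprint = np.zeros((h, w), dtype=bool)
    vec = np.asarray(vector, dtype=float)
    for (x, y), area in zip(centers, areas_um2):
        r_eq = math.sqrt(area / math.pi) / um_per_px
        aspect = rng.uniform(0.7, 1.0)
        r_major = r_eq / math.sqrt(aspect)
        r_minor = r_eq * math.sqrt(aspect)
        rot = rng.uniform(0.0, math.pi)
        rr, cc = draw_ellipse(y, x, r_major, r_minor, shape=(h, w), rotation=rot)
        od_image[rr, cc] += amplitude * vec
        footprint[rr, cc] = True
    return footprint


def render_slide(spec: SlideSpec):
    """Render one synthetic H-DAB slide.

    Cell counts per region are Poisson around density x area; centers are
    uniform in the region polygon with a hard-core distance of one mean
    cell diameter (unless ``spec.overlap``). The returned image is 8-bit
    RGB; :class:`GroundTruth` is exact for the realized placement.

    Returns
    -------
    (image, ground_truth) : (ndarray uint8 (H, W, 3), GroundTruth)
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    od = np.zeros((h, w, 3), dtype=float)
    annotation = spec.annotation()

    mean_diam_px = 2.0 * math.sqrt(spec.cell_area_mean_um2 / math.pi) / spec.um_per_px
    min_dist = 0.0 if spec.overlap else mean_diam_px

    regions: dict[str, RegionTruth] = {}
    for label, poly, density in (
        ("TC", spec.tc_polygon, spec.target_density_tc),
        ("IM", spec.im_polygon, spec.target_density_im),
    ):
        mask = rasterize_region(annotation, label, (h, w))
        area_mm2 = region_area_mm2(mask, spec.um_per_px)
        n = int(rng.poisson(density * area_mm2)) if density > 0 else 0
        centers = _place_centers(rng, poly, n, min_dist)
        areas = _sample_areas(rng, n, spec.cell_area_mean_um2, spec.cell_area_cv)
        footprint = _paint(od, rng, centers, areas, spec.um_per_px, DAB_OD, DAB_AMPLITUDE)
        regions[label] = RegionTruth(
            label=label,
            true_cell_count=n,
            true_positive_area_um2=float(np.count_nonzero(footprint) * spec.um_per_px**2),
            region_area_mm2=area_mm2,
            true_density=n / area_mm2,
            cells=[CellRecord(float(x), float(y), float(a)) for (x, y), a in zip(centers, areas)],
        )

    # hematoxylin-only background nuclei across the whole frame
    frame_mm2 = h * w * spec.um_per_px**2 / 1e6
    n_bg = int(rng.poisson(spec.background_nuclei_density * frame_mm2))
    if n_bg:
        bg_x = rng.uniform(0, w - 1, size=n_bg)
        bg_y = rng.uniform(0, h - 1, size=n_bg)
        bg_areas = _sample_areas(rng, n_bg, spec.cell_area_mean_um2, spec.cell_area_cv)
        _paint(od, rng, np.column_stack([bg_x, bg_y]), bg_areas, spec.um_per_px,
               HEMATOXYLIN_OD, HEMATOXYLIN_AMPLITUDE)

    image = od_to_rgb(od).astype(float)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma * 255.0, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    truth = GroundTruth(regions=regions, artifacts=[], um_per_px=spec.um_per_px)
    if spec.artifact_count > 0:
        image = add_artifacts(image, spec.artifact_count, seed=spec.seed + 1,
                              ground_truth=truth)
    return image, truth


def add_artifacts(
    image: np.ndarray,
    n: int,
    size_range_um2: tuple[float, float] = (5000.0, 20000.0),
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    um_per_px: float | None = None,
    max_cell_object_um2: float = 1000.0,
    allow_overlap: bool = False,
) -> np.ndarray:
    """Stamp DAB-toned smears outside the plausible cell-size range.

    Emulates unspecific staining and mounting artifacts that a pathologist
    would remove manually; the size filter in the measurement stage must
    reject them. Artifacts are logged in ``ground_truth.artifacts`` when a
    ground truth is supplied. ``n=0`` returns an identical copy.

    Raises
    ------
    ParameterError
        If the smallest artifact size does not exceed ``max_cell_object_um2``
        (artifacts must be distinguishable from cells by size alone).
    PlacementError
        If non-overlapping placement w.r.t. recorded cells fails.
    """
    out = np.asarray(image).copy()
    if n == 0:
        return out
    lo, hi = size_range_um2
    if lo <= max_cell_object_um2:
        raise ParameterError(
            f"artifact size minimum {lo} um^2 must exceed the maximum "
            f"cell-object size {max_cell_object_um2} um^2"
        )
    if hi < lo:
        raise ParameterError("size_range_um2 must be (min, max) with min <= max")
    if um_per_px is None:
        um_per_px = ground_truth.um_per_px if ground_truth is not None else 1.0
    rng = np.random.default_rng(seed)
    h, w = out.shape[:2]

    cell_pts = None
    cell_r = 0.0
    if ground_truth is not None and not allow_overlap:
        pts = [
            (c.center_x, c.center_y)
            for region in ground_truth.regions.values()
            for c in region.cells
        ]
        if pts:
            cell_pts = cKDTree(np.asarray(pts))
            cell_r = max(
                math.sqrt(c.area_um2 / math.pi) / um_per_px
                for region in ground_truth.regions.values()
                for c in region.cells
            )

    od = None  # lazily computed; artifacts add DAB in OD space like cells do
    placed = 0
    for _ in range(200 * n):
        if placed == n:
            break
        area = rng.uniform(lo, hi)
        r_eq = math.sqrt(area / math.pi) / um_per_px
        x = rng.uniform(r_eq, w - 1 - r_eq)
        y = rng.uniform(r_eq, h - 1 - r_eq)
        if cell_pts is not None:
            if cell_pts.query_ball_point([x, y], r_eq * 1.3 + cell_r, return_length=True):
                continue
        aspect = rng.uniform(0.5, 1.0)
        rr, cc = draw_ellipse(
            y, x, r_eq / math.sqrt(aspect), r_eq * math.sqrt(aspect),
            shape=(h, w), rotation=rng.uniform(0, math.pi),
        )
        if od is None:
            from .stainquant import rgb_to_od

            od = rgb_to_od(out)
        od[rr, cc] += DAB_AMPLITUDE * np.asarray(DAB_OD)
        out[rr, cc] = od_to_rgb(od[rr, cc])
        if ground_truth is not None:
            ground_truth.artifacts.append(
                {"center_x": float(x), "center_y": float(y), "area_um2": float(area)}
            )
        placed += 1
    if placed < n:
        raise PlacementError(f"placed only {placed} of {n} artifacts without overlap")
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    Densities per marker/region are log-normal with the given median and
    log-scale sigma. The MSI multiplier is applied on the log scale and
    centered (MSI patients x mult^(1-f), MSS x mult^(-f), f = msi_fraction)
    so the cohort-wide median stays at the configured target regardless of
    the effect size.
    """

    n_patients: int = 119
    marker_params: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PARAMS))
    msi_fraction: float = 42 / 119
    msi_density_multiplier: float = 1.5
    stage_probabilities: tuple = DEFAULT_STAGE_PROBABILITIES
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ParameterError("n_patients must be >= 4")
        if not 0.0 <= self.msi_fraction <= 1.0:
            raise ParameterError("msi_fraction must be in [0, 1]")
        if self.msi_density_multiplier < 1.0:
            raise ParameterError("msi_density_multiplier must be >= 1")
        probs = np.asarray(self.stage_probabilities, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("stage_probabilities must be 3 non-negative values summing to 1")
        missing = set(MARKER_COLUMNS) - set(self.marker_params)
        if missing:
            raise ParameterError(f"marker_params missing entries for {sorted(missing)}")
        for key, (median, sigma) in self.marker_params.items():
            if median <= 0 or sigma < 0:
                raise ParameterError(f"marker_params[{key!r}] must have median > 0 and sigma >= 0")


def generate_cohort(spec: CohortSpec):
    """Draw a synthetic cohort: density table + patient metadata table.

    Returns
    -------
    (densities, metadata) : (DataFrame, DataFrame)
        ``densities``: patient_id, CD3_TC, CD3_IM, CD8_TC, CD8_IM
        (cells/mm**2, all > 0). ``metadata``: patient_id,
        stage in {I, II, III}, msi in {MSS, MSI}.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]
    msi = rng.random(n) < spec.msi_fraction
    stages = rng.choice(["I", "II", "III"], size=n, p=np.asarray(spec.stage_probabilities, float))

    log_mult = math.log(spec.msi_density_multiplier)
    f = spec.msi_fraction
    data = {"patient_id": ids}
    for marker in MARKER_COLUMNS:
        median, sigma = spec.marker_params[marker]
        log_d = math.log(median) + sigma * rng.standard_normal(n)
        if marker in MSI_AFFECTED and log_mult > 0:
            log_d = log_d + np.where(msi, (1.0 - f) * log_mult, -f * log_mult)
        data[marker] = np.exp(log_d)
    densities = pd.DataFrame(data)
    metadata = pd.DataFrame(
        {"patient_id": ids, "stage": stages, "msi": np.where(msi, "MSI", "MSS")}
    )
    return densities, metadata
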