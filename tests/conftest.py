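import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tilquant.synthio import MARKER_COLUMNS, CohortSpec, SlideSpec, generate_cohort, render_slide

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# Published reference cohort of 119 stage I-III colon cancers: number of
# patients with 0..4 marker-regions at or above the cohort 75th percentile,
# and the per-stratum count of patients high for each marker-region.
REFERENCE_N = 119
REFERENCE_STRATUM_SIZES = (69, 14, 14, 11, 11)
REFERENCE_STRATUM_HIGHS = {
    "CD3_TC": (0, 1, 9, 8, 11),
    "CD8_TC": (0, 2, 9, 8, 11),
    "CD3_IM": (0, 5, 6, 8, 11),
    "CD8_IM": (0, 6, 4, 9, 11),
}
# High-immune-score patients by MSI status in the same cohort.
REFERENCE_MSI_HIGH = (12, 42)  # 12 of 42 MSI tumors
REFERENCE_MSS_HIGH = (10, 77)  # 10 of 77 MSS tumors


def flags_from_stratum_marginals(stratum_sizes, stratum_highs):
    """Build a per-patient boolean flag matrix consistent with per-stratum
    marginals: in stratum k every patient has exactly k high markers and the
    per-marker high counts match. Greedy assignment: each patient takes the
    k markers with the largest remaining demand.
    """
    rows = []
    for k, size in enumerate(stratum_sizes):
        demand = {m: stratum_highs[m][k] for m in MARKER_COLUMNS}
        assert sum(demand.values()) == k * size, f"infeasible marginals in stratum {k}"
        for _ in range(size):
            chosen = sorted(MARKER_COLUMNS, key=lambda m: -demand[m])[:k]
            for m in chosen:
                demand[m] -= 1
            rows.append({m: m in chosen for m in MARKER_COLUMNS})
        assert all(v == 0 for v in demand.values()), f"greedy failed in stratum {k}"
    flags = pd.DataFrame(rows)
    flags.index = [f"P{i + 1:04d}" for i in range(len(flags))]
    return flags


@pytest.fixture(scope="session")
def reference_flags():
    return flags_from_stratum_marginals(REFERENCE_STRATUM_SIZES, REFERENCE_STRATUM_HIGHS)


@pytest.fixture(scope="session")
def small_slide():
    """Small noiseless slide with exact-area (cv=0) non-overlapping cells."""
    spec = SlideSpec(
        width_px=700,
        height_px=700,
        um_per_px=1.0,
        tc_polygon=[(20, 20), (330, 20), (330, 330), (20, 330)],
        im_polygon=[(370, 370), (680, 370), (680, 680), (370, 680)],
        target_density_tc=400.0,
        target_density_im=800.0,
        cell_area_cv=0.0,
        background_nuclei_density=400.0,
        noise_sigma=0.0,
        seed=11,
    )
    image, truth = render_slide(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def cohort_tables():
    return generate_cohort(CohortSpec(seed=42))
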