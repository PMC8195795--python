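"""Percentile thresholds, high/low flags and the three-tier immune score.

Given a cohort table of per-patient densities for the four marker-region
combinations (CD3 and CD8, each in tumor center TC and invasive margin IM),
the score is built in three steps:

1. per marker-region, compute the cohort 25th/50th/75th percentiles;
2. flag a patient "high" for a marker iff density >= the 75th percentile
   (inclusive); the number of high markers (0-4) is the I0-I4 stratum;
3. map the stratum to the immune-score group:
   {0, 1} -> Low, {2} -> Intermediate, {3, 4} -> High.

Thresholds are calibrated in-cohort by default; externally supplied
(frozen) thresholds are accepted so new patients can be scored against a
reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .synthio import MARKER_COLUMNS

GROUP_OF_COUNT = {0: "Low", 1: "Low", 2: "Intermediate", 3: "High", 4: "High"}
GROUP_ORDER = ("Low", "Intermediate", "High")

#: numpy quantile methods exposed to callers; "linear" interpolates between
#: order statistics at h = (n-1) q, "inverted_cdf" is the nearest-rank rule.
QUANTILE_METHODS = ("linear", "inverted_cdf")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"density table is missing columns {missing}")
    if len(table) < 4:
        raise DataError(f"cohort must have >= 4 patients, got {len(table)}")
    for col in MARKER_COLUMNS:
        bad = table.index[table[col].isna()]
        if len(bad):
            raise DataError(f"NaN density in {col} for patient(s) {list(bad[:5])}")
        if (table[col] < 0).any():
            raise DataError(f"negative density in {col}")
    return table


@dataclass
class CohortThresholds:
    """Per-marker percentile cutoffs (cells/mm**2) over one cohort."""

    quantiles: pd.DataFrame  # index: probabilities, columns: markers
    quantile_method: str = "linear"

    def p75(self, marker: str) -> float:
        return float(self.quantiles.loc[0.75, marker])

    def report(self) -> pd.DataFrame:
        """Threshold table with densities rounded to whole cells/mm**2."""
        out = self.quantiles.round(0).astype(int)
        out.index = [f"{int(q * 100)}th" for q in self.quantiles.index]
        return out


def cohort_percentiles(
    table: pd.DataFrame,
    q=(0.25, 0.5, 0.75),
    method: str = "linear",
) -> CohortThresholds:
    """Empirical per-marker quantiles over the cohort.

    The default "linear" method interpolates between order statistics at
    h = (n-1) q, so the 0.5 quantile equals the median.
    """
    table = _validate_table(table)
    q = list(q)
    if any(not 0.0 < p < 1.0 for p in q):
        raise ParameterError("quantile probabilities must lie strictly in (0, 1)")
    if method not in QUANTILE_METHODS:
        raise ParameterError(f"quantile method must be one of {QUANTILE_METHODS}")
    values = {
        m: np.quantile(np.asarray(table[m], dtype=float), q, method=method)
        for m in MARKER_COLUMNS
    }
    frame = pd.DataFrame(values, index=q)
    return CohortThresholds(quantiles=frame, quantile_method=method)


def flag_high(density, p75: float):
    """High immune response iff density >= the 75th percentile (inclusive)."""
    if not np.isfinite(p75):
        raise ParameterError("p75 threshold must be finite")
    return np.asarray(density) >= p75 if np.ndim(density) else bool(density >= p75)


def classify_immune_score(high_count: int) -> str:
    """Map the number of high markers (0-4) to Low / Intermediate / High."""
    count = int(high_count)
    if count != high_count or count not in GROUP_OF_COUNT:
        raise ParameterError(f"high_count must be an integer in 0..4, got {high_count!r}")
    return GROUP_OF_COUNT[count]


@dataclass
class ImmuneScoreResult:
    """Scored cohort: per-patient flags, strata and groups, plus thresholds."""

    per_patient: pd.DataFrame  # index patient_id; <marker>_high flags, high_count, stratum, group
    thresholds: CohortThresholds | None = None
    tie_counts: dict = field(default_factory=dict)

    def group_sizes(self) -> pd.Series:
        counts = self.per_patient["group"].value_counts()
        return counts.reindex(GROUP_ORDER, fill_value=0)

    def group_percentages(self, decimals: int = 1) -> pd.Series:
        return (100.0 * self.group_sizes() / len(self.per_patient)).round(decimals)


def score_from_flags(flags: pd.DataFrame) -> ImmuneScoreResult:
    """Build an ImmuneScoreResult from an explicit boolean flag matrix.

    ``flags``: index patient_id, one boolean column per marker in
    ``MARKER_COLUMNS``. Used when flags come from an external source
    rather than in-cohort thresholds.
    """
    missing = [c for c in MARKER_COLUMNS if c not in flags.columns]
    if missing:
        raise DataError(f"flag matrix is missing columns {missing}")
    per_patient = flags[list(MARKER_COLUMNS)].astype(bool).copy()
    per_patient.columns = [f"{m}_high" for m in MARKER_COLUMNS]
    per_patient["high_count"] = per_patient.sum(axis=1).astype(int)
    per_patient["stratum"] = per_patient["high_count"].map(lambda k: f"I{k}")
    per_patient["group"] = per_patient["high_count"].map(classify_immune_score)
    return ImmuneScoreResult(per_patient=per_patient)


def score_cohort(
    table: pd.DataFrame,
    thresholds: CohortThresholds | None = None,
    quantile_method: str = "linear",
) -> ImmuneScoreResult:
    """Score a cohort density table (index or column ``patient_id``).

    Thresholds are computed on this same cohort unless frozen thresholds
    from a reference cohort are supplied.
    """
    if "patient_id" in table.columns:
        if table["patient_id"].duplicated().any():
            dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
            raise DataError(f"duplicate patient_id(s): {dupes}")
        table = table.set_index("patient_id")
    table = _validate_table(table)
    if thresholds is None:
        thresholds = cohort_percentiles(table, method=quantile_method)

    flags = pd.DataFrame(index=table.index)
    ties = {}
    for marker in MARKER_COLUMNS:
        cut = thresholds.p75(marker)
        flags[marker] = flag_high(table[marker].to_numpy(), cut)
        ties[marker] = int((table[marker] == cut).sum())
    result = score_from_flags(flags)
    result.thresholds = thresholds
    result.tie_counts = ties
    return result


def cross_tab_regions(result: ImmuneScoreResult) -> pd.DataFrame:
    """Stratum x marker cross-tabulation of low/high patients.

    Rows are the I0-I4 strata ("k of 4") plus a total row; columns are
    "<marker> Low"/"<marker> High" counts plus the stratum size.
    """
    pp = result.per_patient
    rows = {}
    for k in range(5):
        sub = pp[pp["high_count"] == k]
        row = {"patients": len(sub)}
        for marker in MARKER_COLUMNS:
            high = int(sub[f"{marker}_high"].sum())
            row[f"{marker} Low"] = len(sub) - high
            row[f"{marker} High"] = high
        rows[f"{k} of 4"] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.loc["Total"] = out.sum(axis=0)
    return out


def group_size_summary(result: ImmuneScoreResult) -> dict:
    """Group sizes and percentages in a JSON-friendly shape."""
    sizes = result.group_sizes()
    pct = result.group_percentages()
    return {
        "n": int(len(result.per_patient)),
        "groups": {g: {"n": int(sizes[g]), "percent": float(pct[g])} for g in GROUP_ORDER},
        "strata": {
            f"I{k}": int((result.per_patient["high_count"] == k).sum()) for k in range(5)
        },
        "tie_counts": result.tie_counts,
    }
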