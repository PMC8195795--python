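"""Association statistics for the scored cohort.

Two tests mirror common practice for this kind of cohort: Pearson
chi-square for immune-score group versus categorical clinicopathological
variables (stage, MSI status), and the Mann-Whitney U test for density
differences between MSS and MSI tumors. Two-tailed throughout; alpha =
0.05. No multiple-testing correction is applied — p-values are reported
as-is, and the report says so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, JoinError, ParameterError
from .synthio import MARKER_COLUMNS

ALPHA = 0.05

#: Largest min(n1, n2) for which the exact Mann-Whitney null distribution
#: is enumerated (tie-free samples only); larger samples use the normal
#: approximation with tie-corrected variance and 0.5 continuity correction.
EXACT_ENUMERATION_CUTOFF = 8


@dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    counts: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataError("contingency counts must be non-negative")
        if arr.sum() <= 0:
            raise DataError("contingency table grand total must be > 0")


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of two density samples."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    mode: str = "auto"


def chi_square(table, yates: bool = False):
    """Pearson chi-square test of independence.

    Parameters
    ----------
    table : ContingencyTable, DataFrame or 2-D array
    yates : bool
        Apply the Yates continuity correction (2x2 tables only; off by
        default for tables of any size).

    Returns
    -------
    (statistic, df, p)
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts.to_numpy(dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ParameterError(f"need an r>=2 x c>=2 table, got shape {counts.shape}")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=yates)
    return float(stat), int(df), float(p)


def mann_whitney(sample_a, sample_b, mode: str = "auto") -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    mode:
      * "exact" — full enumeration of the null distribution (requires a
        tie-free pooled sample);
      * "asymptotic" — normal approximation with tie-corrected variance
        and 0.5 continuity correction;
      * "auto" — exact when min(n) <= 8 and the pooled sample is tie-free,
        asymptotic otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all pooled values identical; Mann-Whitney p set to 1", stacklevel=2)
        u = a.size * b.size / 2.0
        return GroupComparison("a", "b", a.size, b.size, u, 1.0,
                               float(np.median(a)), float(np.median(b)), mode="degenerate")

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        use_exact = min(a.size, b.size) <= EXACT_ENUMERATION_CUTOFF and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ParameterError("exact mode requires a tie-free pooled sample")
        use_exact = True
    elif mode == "asymptotic":
        use_exact = False
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(
        label_a="a", label_b="b", n_a=int(a.size), n_b=int(b.size),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mode=method,
    )


def _score_table(scores: pd.DataFrame, meta: pd.DataFrame, column: str,
                 pool: dict | None = None) -> ContingencyTable:
    merged = scores.join(meta[column], how="inner")
    col = merged[column] if pool is None else merged[column].map(lambda v: pool.get(v, v))
    tab = pd.crosstab(merged["group"], col)
    order = [g for g in ("Low", "Intermediate", "High") if g in tab.index]
    return ContingencyTable(tab.loc[order])


def association_report(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    densities: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """All association tests for a scored cohort.

    * chi-square of immune-score group vs stage, both on the full I/II/III
      table and with stage I-II pooled (the attribution of a single stage
      p-value to one of the two shapes is ambiguous, so both are reported);
    * chi-square of group vs MSI status, and of high-vs-not-high score vs
      MSI;
    * Mann-Whitney per marker-region between MSS and MSI densities.

    Parameters
    ----------
    scores : per-patient frame with a "group" column (index patient_id)
    metadata : frame with columns stage, msi (index or column patient_id)
    densities : density table (index or column patient_id)

    Returns
    -------
    (report, tables) : tidy DataFrame of tests and the dict of
    contingency tables / comparisons behind them.
    """
    scores = scores.set_index("patient_id") if "patient_id" in scores.columns else scores
    metadata = metadata.set_index("patient_id") if "patient_id" in metadata.columns else metadata
    densities = densities.set_index("patient_id") if "patient_id" in densities.columns else densities

    orphans = scores.index.symmetric_difference(metadata.index)
    if len(orphans):
        raise JoinError(f"patient ids do not align between scores and metadata: {list(orphans[:10])}")
    orphans = scores.index.symmetric_difference(densities.index)
    if len(orphans):
        raise JoinError(f"patient ids do not align between scores and densities: {list(orphans[:10])}")

    rows = []
    tables: dict = {}

    def add_chi(name, ctab):
        counts = ctab.counts.to_numpy()
        if (
            counts.ndim != 2
            or min(counts.shape) < 2
            or (counts.sum(axis=0) == 0).any()
            or (counts.sum(axis=1) == 0).any()
        ):
            # a level is absent in this cohort (e.g. nobody scored High);
            # the test is undefined, so it is reported as untestable
            rows.append({
                "test": "chi_square", "comparison": name,
                "shape": "x".join(map(str, counts.shape)),
                "statistic": np.nan, "df": np.nan, "p_value": np.nan,
                "significant": False,
            })
            return
        stat, df, p = chi_square(ctab)
        tables[name] = ctab
        rows.append({
            "test": "chi_square", "comparison": name,
            "shape": "x".join(map(str, ctab.counts.shape)),
            "statistic": stat, "df": df, "p_value": p,
            "significant": p < ALPHA,
        })

    if "stage" in metadata.columns:
        add_chi("group_vs_stage", _score_table(scores, metadata, "stage"))
        add_chi("group_vs_stage_I-II_pooled",
                _score_table(scores, metadata, "stage", pool={"I": "I-II", "II": "I-II"}))
    if "msi" in metadata.columns:
        add_chi("group_vs_msi", _score_table(scores, metadata, "msi"))
        merged = scores.join(metadata["msi"], how="inner")
        high = (merged["group"] == "High").map({True: "High", False: "Not high"})
        tab = pd.crosstab(merged["msi"], high)
        add_chi("high_score_vs_msi", ContingencyTable(tab))

        for marker in MARKER_COLUMNS:
            joined = densities[[marker]].join(metadata["msi"], how="inner")
            mss = joined.loc[joined["msi"] == "MSS", marker].to_numpy()
            msi = joined.loc[joined["msi"] == "MSI", marker].to_numpy()
            if mss.size == 0 or msi.size == 0:
                continue
            cmp = mann_whitney(mss, msi)
            cmp.label_a, cmp.label_b = "MSS", "MSI"
            tables[f"mwu_{marker}"] = cmp
            rows.append({
                "test": "mann_whitney", "comparison": f"{marker}_MSS_vs_MSI",
                "shape": f"{cmp.n_a}+{cmp.n_b}",
                "statistic": cmp.u_statistic, "df": np.nan, "p_value": cmp.p_value,
                "significant": cmp.p_value < ALPHA,
            })

    report = pd.DataFrame(rows)
    report.attrs["note"] = "p-values are unadjusted for multiple testing"
    return report, tables
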