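"""Feature-table statistics for public-data reanalyses.

Covers the downstream arc of a reverse-metabolomics reanalysis: blank
filtering of a feature x sample peak-area table, two-group Wilcoxon
rank-sum comparisons with log10 fold changes, a simple monotone time-trend
report, and Metabolomics Standards Initiative confidence assignment from
retention-time and ion-mobility drift agreement with authentic standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Pseudo-area added to fold-change denominators so zero-area groups stay finite.
EPSILON_AREA = 1.0


@dataclass
class FeatureTable:
    """A feature x sample peak-area matrix with feature and sample metadata.

    ``features``: DataFrame indexed by feature_id with columns mz, rt and
    optionally drift. ``samples``: DataFrame indexed by sample_id with
    columns group and role (sample / blank / control). ``areas``: DataFrame
    of nonnegative peak areas, features as rows, samples as columns.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.areas.index) != list(self.features.index):
            raise ValueError("areas rows must align with the feature table")
        if list(self.areas.columns) != list(self.samples.index):
            raise ValueError("areas columns must align with the sample table")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be nonnegative")

    @classmethod
    def from_csv(cls, path, sample_table: pd.DataFrame) -> "FeatureTable":
        """Read a feature-finder CSV export (feature id, m/z, RT, area columns)."""
        raw = pd.read_csv(path)
        meta_cols = [c for c in ("feature_id", "mz", "rt", "drift") if c in raw.columns]
        frame = raw.set_index("feature_id")
        features = frame[[c for c in meta_cols if c != "feature_id"]]
        areas = frame[[c for c in frame.columns if c in sample_table.index]]
        return cls(features=features, samples=sample_table.loc[areas.columns], areas=areas)

    def to_csv(self, path) -> None:
        out = pd.concat([self.features, self.areas], axis=1)
        out.index.name = "feature_id"
        out.to_csv(path)

    def subset_features(self, feature_ids: Sequence) -> "FeatureTable":
        return FeatureTable(
            features=self.features.loc[feature_ids],
            samples=self.samples,
            areas=self.areas.loc[feature_ids],
        )


def blank_filter(
    table: FeatureTable, ratio_min: float = 3.0, epsilon: float = EPSILON_AREA
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Remove features whose sample/blank abundance ratio falls below a floor.

    A feature is retained iff ``mean(sample areas) / max(mean blank area,
    epsilon) >= ratio_min``. Returns the filtered table and an audit frame
    listing every removed feature with its ratio. Raises if the table has no
    blank samples — skipping the filter must be an explicit caller decision.
    """
    blank_cols = table.samples.index[table.samples["role"] == "blank"]
    sample_cols = table.samples.index[table.samples["role"] == "sample"]
    if len(blank_cols) == 0:
        raise ValueError(
            "feature table has no blank samples; skip blank filtering explicitly "
            "instead of calling blank_filter"
        )
    blank_mean = table.areas[blank_cols].mean(axis=1)
    sample_mean = table.areas[sample_cols].mean(axis=1)
    ratio = sample_mean / np.maximum(blank_mean, epsilon)
    keep = ratio >= ratio_min
    audit = pd.DataFrame(
        {
            "sample_mean": sample_mean[~keep],
            "blank_mean": blank_mean[~keep],
            "ratio": ratio[~keep],
        }
    )
    return table.subset_features(table.areas.index[keep]), audit


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p-value).

    Uses exact enumeration when the smaller group has at most 8 observations
    and the data are tie-free, otherwise the normal approximation with tie
    and continuity corrections. Identical pooled values yield p = 1 with a
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_x = float(ranks[: x.size].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return w_x, 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    result = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w_x, float(min(result.pvalue, 1.0))


def group_compare(
    table: FeatureTable,
    grouping: Tuple[str, str],
    alpha: float = 0.05,
    correction: Optional[str] = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison on non-blank samples.

    Fold change is ``log10((mean_A + eps) / (mean_B + eps))`` with a 1.0
    pseudo-area. Significance is uncorrected ``p < alpha`` by default
    (mirroring common reanalysis practice); ``correction='bh'`` applies
    Benjamini-Hochberg and flags on the adjusted values instead.
    """
    group_a, group_b = grouping
    usable = table.samples[table.samples["role"] != "blank"]
    available = sorted(usable["group"].dropna().unique())
    for label in grouping:
        if label not in available:
            raise ValueError(f"group {label!r} not present; available: {available}")
    cols_a = usable.index[usable["group"] == group_a]
    cols_b = usable.index[usable["group"] == group_b]
    rows = []
    for feature_id in table.areas.index:
        x = table.areas.loc[feature_id, cols_a].to_numpy(dtype=float)
        y = table.areas.loc[feature_id, cols_b].to_numpy(dtype=float)
        statistic, p = wilcoxon_rank_sum(x, y)
        log10_fc = float(
            np.log10((x.mean() + EPSILON_AREA) / (y.mean() + EPSILON_AREA))
        )
        rows.append(
            {
                "feature_id": feature_id,
                "log10_fold_change": log10_fc,
                "statistic": statistic,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows).set_index("feature_id")
    if correction == "bh":
        result["p_adjusted"] = sps.false_discovery_control(result["p_value"], method="bh")
        result["significant"] = result["p_adjusted"] < alpha
    elif correction is None:
        result["significant"] = result["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}; use None or 'bh'")
    return result


def time_trend(
    values: Sequence[float], times: Sequence[float], n_bins: int = 2
) -> Dict[str, float]:
    """Monotone-trend report: first-vs-last time-bin Wilcoxon plus Spearman rho.

    The trend test is not standardized in reanalysis practice, so both a
    two-bin rank-sum comparison and a rank correlation are reported and the
    caller chooses which to quote.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    order = np.argsort(times, kind="stable")
    values, times = values[order], times[order]
    edges = np.linspace(times[0], times[-1], n_bins + 1)
    first = values[times <= edges[1]]
    last = values[times >= edges[-2]]
    _, p_bins = wilcoxon_rank_sum(first, last)
    rho, p_rho = sps.spearmanr(times, values)
    return {
        "first_bin_mean": float(first.mean()),
        "last_bin_mean": float(last.mean()),
        "wilcoxon_p_first_vs_last": float(p_bins),
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
    }


@dataclass(frozen=True)
class ConfidenceAssignment:
    """MSI annotation tier for one feature."""

    feature_id: str
    msi_level: int  # 1 or 2
    evidence: str  # 'ms2+rt+drift' or 'ms2_only'
    reason: str = ""


def assign_confidence(
    observations: pd.DataFrame,
    standards: pd.DataFrame,
    rt_tol: float = 0.1,
    drift_tol: float = 0.02,
) -> List[ConfidenceAssignment]:
    """Assign MSI levels from RT and drift agreement with authentic standards.

    ``observations`` needs columns feature_id, compound, rt, drift and
    ms2_match (bool); ``standards`` is indexed by compound with columns rt
    and drift. Level 1 requires an MS2 match plus RT and drift agreement
    within tolerance; everything else (including compounds missing from the
    standards table) stays level 2. A feature without an MS2 match is never
    upgraded.
    """
    assignments: List[ConfidenceAssignment] = []
    for _, row in observations.iterrows():
        feature_id = str(row["feature_id"])
        if not bool(row["ms2_match"]):
            assignments.append(
                ConfidenceAssignment(feature_id, 2, "none", "no MS2 match")
            )
            continue
        compound = row["compound"]
        if compound not in standards.index:
            assignments.append(
                ConfidenceAssignment(feature_id, 2, "ms2_only", "no standard")
            )
            continue
        std = standards.loc[compound]
        rt_ok = (
            row["rt"] is not None
            and not pd.isna(row["rt"])
            and abs(float(row["rt"]) - float(std["rt"])) <= rt_tol
        )
        drift_ok = (
            row.get("drift") is not None
            and not pd.isna(row.get("drift"))
            and abs(float(row["drift"]) - float(std["drift"])) <= drift_tol
        )
        if rt_ok and drift_ok:
            assignments.append(
                ConfidenceAssignment(feature_id, 1, "ms2+rt+drift")
            )
        else:
            parts = []
            if not rt_ok:
                parts.append("rt outside tolerance")
            if not drift_ok:
                parts.append("drift outside tolerance")
            assignments.append(
                ConfidenceAssignment(feature_id, 2, "ms2_only", "; ".join(parts))
            )
    return assignments
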