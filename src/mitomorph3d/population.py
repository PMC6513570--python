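"""Population-level distribution analytics for organelle metrics.

Mitochondria within a muscle act as a population: the informative changes in
disease are often in the tails rather than the mean. This module implements
the percentile-based tail classes ("simple"/"complex" by MCI and
"small"/"large" by volume, relative to the pooled healthy-control
distribution), multi-level coefficients of variation (within-cell,
between-cell, between-person), mitochondrial volume density over two
sarcomeres, and distribution-shape summaries.

Percentiles use linear interpolation between order statistics (the "type 7"
rule, numpy's default), pinned so that on a pooled control population of
distinct values whose size is a multiple of ten, exactly 10% of organelles
classify simple by construction. Class membership uses strict inequalities:
a value exactly at a threshold falls in the middle class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationThresholds",
    "CohortSummary",
    "percentile_thresholds",
    "classify_values",
    "classify_population",
    "cv_levels",
    "volume_density",
    "distribution_moments",
    "cumulative_distribution",
]


@dataclass(frozen=True)
class PopulationThresholds:
    """10th/90th percentile cut points of the pooled control population."""

    q10_mci: float
    q90_mci: float
    q10_vol: float
    q90_vol: float

    def __post_init__(self):
        if not (self.q10_mci < self.q90_mci and self.q10_vol < self.q90_vol):
            raise ValueError("degenerate thresholds: q10 must be < q90 for each metric")


@dataclass
class CohortSummary:
    """Per-individual morphological feature vector."""

    subject_id: str
    group: str
    pct_simple: float
    pct_complex: float
    pct_small: float
    pct_large: float
    median_mci: float
    median_volume: float
    volume_density_pct: float = np.nan
    nanotunnels_per_100: float = np.nan


def percentile_thresholds(
    control_metrics: pd.DataFrame,
    mci_col: str = "mci",
    vol_col: str = "volume_um3",
    lower: float = 10.0,
    upper: float = 90.0,
) -> PopulationThresholds:
    """Percentile cut points of the pooled control metrics (type 7 rule)."""
    mci_vals = np.asarray(control_metrics[mci_col].dropna(), dtype=float)
    vol_vals = np.asarray(control_metrics[vol_col].dropna(), dtype=float)
    if mci_vals.size < 10 or vol_vals.size < 10:
        raise ValueError("need at least 10 pooled control organelles")
    return PopulationThresholds(
        q10_mci=float(np.quantile(mci_vals, lower / 100.0)),
        q90_mci=float(np.quantile(mci_vals, upper / 100.0)),
        q10_vol=float(np.quantile(vol_vals, lower / 100.0)),
        q90_vol=float(np.quantile(vol_vals, upper / 100.0)),
    )


def classify_values(values, q10: float, q90: float) -> np.ndarray:
    """Three-way tail classification with strict inequalities.

    Returns "low", "mid" or "high" per value; ties at a threshold are "mid".
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, "mid", dtype=object)
    out[values < q10] = "low"
    out[values > q90] = "high"
    return out


def classify_population(
    metrics: pd.DataFrame,
    thresholds: PopulationThresholds,
    mci_col: str = "mci",
    vol_col: str = "volume_um3",
    group_col: str = "group",
    subject_col: str = "subject_id",
    control_group: str = "control",
):
    """Classify every organelle and summarise proportions.

    Adds per-organelle ``mci_class`` / ``vol_class`` columns and returns
    (classified table, per-subject summary, per-group pooled summary). The
    group summary reports percent simple/complex/small/large and the fold
    elevation of the simple proportion over the 10% control baseline.
    """
    df = metrics.copy()
    df["mci_class"] = classify_values(df[mci_col], thresholds.q10_mci, thresholds.q90_mci)
    df["vol_class"] = classify_values(df[vol_col], thresholds.q10_vol, thresholds.q90_vol)
    df["mci_class"] = df["mci_class"].map({"low": "simple", "mid": "mid", "high": "complex"})
    df["vol_class"] = df["vol_class"].map({"low": "small", "mid": "mid", "high": "large"})

    def _summarise(sub: pd.DataFrame) -> dict:
        n = len(sub)
        return {
            "n": n,
            "pct_simple": 100.0 * (sub["mci_class"] == "simple").mean(),
            "pct_complex": 100.0 * (sub["mci_class"] == "complex").mean(),
            "pct_small": 100.0 * (sub["vol_class"] == "small").mean(),
            "pct_large": 100.0 * (sub["vol_class"] == "large").mean(),
            "median_mci": float(sub[mci_col].median()),
            "median_volume": float(sub[vol_col].median()),
        }

    per_subject = pd.DataFrame(
        [
            {subject_col: sid, group_col: sub[group_col].iloc[0], **_summarise(sub)}
            for sid, sub in df.groupby(subject_col, sort=True)
        ]
    )
    per_group = pd.DataFrame(
        [{group_col: grp, **_summarise(sub)} for grp, sub in df.groupby(group_col, sort=True)]
    )
    baseline = 10.0
    if control_group in set(per_group[group_col]):
        baseline = float(
            per_group.loc[per_group[group_col] == control_group, "pct_simple"].iloc[0]
        )
    per_group["simple_fold_vs_control"] = per_group["pct_simple"] / baseline if baseline > 0 else np.nan
    return df, per_subject, per_group


@dataclass
class CVLevels:
    """Coefficients of variation at the three nesting levels (percent)."""

    within_cell: pd.Series  # per (subject, cell) CV
    between_cell: pd.Series  # per subject: CV of its cell means
    between_person: float  # CV of person means

    @property
    def within_cell_range(self) -> tuple[float, float]:
        return float(self.within_cell.min()), float(self.within_cell.max())

    @property
    def between_cell_range(self) -> tuple[float, float]:
        return float(self.between_cell.min()), float(self.between_cell.max())


def cv_levels(
    metrics: pd.DataFrame,
    value_col: str,
    subject_col: str = "subject_id",
    cell_col: str = "cell_id",
) -> CVLevels:
    """Multi-level coefficients of variation, natural scale, in percent.

    within-cell: SD/mean of organelle values per cell; between-cell: per
    subject, CV of that subject's cell means; between-person: CV of subject
    means. Cells with a single organelle are excluded with a warning.
    """
    import warnings

    df = metrics[[subject_col, cell_col, value_col]].dropna()
    sizes = df.groupby([subject_col, cell_col])[value_col].size()
    singletons = sizes[sizes < 2]
    if len(singletons):
        warnings.warn(
            f"excluding {len(singletons)} single-organelle cell(s) from within-cell CV",
            stacklevel=2,
        )
        keep = sizes[sizes >= 2].index
        df = df.set_index([subject_col, cell_col]).loc[keep].reset_index()
    grouped = df.groupby([subject_col, cell_col])[value_col]
    within = 100.0 * grouped.std(ddof=1) / grouped.mean()
    cell_means = grouped.mean()
    by_subject = cell_means.groupby(level=0)
    if (by_subject.size() < 2).all():
        raise ValueError("need >= 2 cells for at least one subject")
    between_cell = 100.0 * by_subject.std(ddof=1) / by_subject.mean()
    person_means = df.groupby(subject_col)[value_col].mean()
    if len(person_means) < 2:
        raise ValueError("need >= 2 subjects for between-person CV")
    between_person = float(100.0 * person_means.std(ddof=1) / person_means.mean())
    return CVLevels(within, between_cell.dropna(), between_person)


def volume_density(organelle_volumes, fiber_volume: float) -> float:
    """Percent of fiber volume (over two sarcomeres) occupied by mitochondria."""
    if fiber_volume <= 0:
        raise ValueError("fiber_volume must be > 0")
    total = float(np.sum(np.asarray(list(organelle_volumes), dtype=float)))
    if total > fiber_volume:
        raise ValueError(
            "total mitochondrial volume exceeds fiber volume: segmentation inconsistency"
        )
    return 100.0 * total / fiber_volume


def distribution_moments(values, kurtosis_convention: str = "raw") -> dict:
    """Moment-based skewness (g1) and kurtosis of a sample.

    ``kurtosis_convention`` "raw" gives Pearson kurtosis (normal = 3),
    "excess" gives Fisher kurtosis (normal = 0).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for shape moments")
    if kurtosis_convention not in {"raw", "excess"}:
        raise ValueError("kurtosis_convention must be 'raw' or 'excess'")
    kurt = stats.kurtosis(values, fisher=(kurtosis_convention == "excess"), bias=True)
    return {
        "skewness": float(stats.skew(values, bias=True)),
        "kurtosis": float(kurt),
    }


def cumulative_distribution(values) -> pd.DataFrame:
    """Empirical CDF as sorted (value, fraction <= value) pairs."""
    values = np.sort(np.asarray(list(values), dtype=float))
    if values.size == 0:
        raise ValueError("need at least one value")
    frac = np.arange(1, values.size + 1) / values.size
    return pd.DataFrame({"value": values, "cumulative_fraction": frac})
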