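"""LLOQ imputation, missingness accounting, ranking and feature building.

Below-quantification values are imputed at the analyte's LLOQ (the standard
practice for this assay class); other kinds of absence are treated as data
errors because the generator produces only LLOQ censoring. Ranking uses
mid-ranks and is performed within analyte across all observations of both
states, matching the ANOVA-on-ranks construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ConcentrationTable, IntegrityError, ValidationError

__all__ = [
    "MissingnessSummary",
    "impute_lloq",
    "rank_transform",
    "FeatureMatrix",
    "to_feature_matrix",
    "per_mouse_means",
]


@dataclass
class MissingnessSummary:
    """Below-LLOQ counts computed before imputation."""

    n_missing: int
    n_total: int
    per_analyte: dict[str, int] = field(default_factory=dict)

    @property
    def pct_missing(self) -> float:
        """Percentage of missing slots, rounded to 1 decimal."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_missing / self.n_total, 1)

    def to_dict(self) -> dict:
        return {
            "n_missing": self.n_missing,
            "n_total": self.n_total,
            "pct_missing": self.pct_missing,
            "per_analyte": dict(self.per_analyte),
        }


def impute_lloq(
    table: ConcentrationTable, lloq: dict[str, float] | np.ndarray
) -> tuple[ConcentrationTable, MissingnessSummary]:
    """Replace absent (below-LLOQ) concentrations by the analyte's LLOQ.

    Returns the imputed table and a :class:`MissingnessSummary` computed on
    the pre-imputation counts. Non-missing records are untouched; an absent
    value without ``below_lloq`` is an integrity error (a non-censoring
    loss, which this pipeline does not model).
    """
    df = table.df.copy()
    if isinstance(lloq, dict):
        lloq_map = {a: float(lloq[a]) for a in table.panel}
    else:
        arr = np.asarray(lloq, dtype=float)
        if arr.shape != (len(table.panel),):
            raise ValidationError("lloq must map every panel analyte")
        lloq_map = dict(zip(table.panel, arr))

    absent = df["concentration_nM"].isna()
    if (absent & ~df["below_lloq"].astype(bool)).any():
        raise IntegrityError("absent concentration with below_lloq=False is not imputable")

    per_analyte = (
        df.loc[absent, "analyte"].value_counts().reindex(list(table.panel), fill_value=0)
    )
    summary = MissingnessSummary(
        n_missing=int(absent.sum()),
        n_total=len(df),
        per_analyte={a: int(per_analyte[a]) for a in table.panel},
    )
    if absent.any():
        df.loc[absent, "concentration_nM"] = df.loc[absent, "analyte"].map(lloq_map)
        df.loc[absent, "imputed"] = True
    return ConcentrationTable(df, table.panel), summary


def rank_transform(values) -> np.ndarray:
    """Mid-ranks in 1..n (ties get the mean of their rank positions)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("rank_transform requires at least one value")
    if not np.isfinite(arr).all():
        raise ValueError("rank_transform requires finite values")
    return stats.rankdata(arr, method="average")


@dataclass
class FeatureMatrix:
    """Wide (mouse, sample) x analyte matrix for correlation and ML stages.

    ``frame`` is indexed by (mouse_id, state, sample_index) and has one
    column per panel analyte; ``scaling`` records whether columns are raw
    imputed nM ("none") or pooled z-scores ("zscore").
    """

    frame: pd.DataFrame
    scaling: str = "none"

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def rows_for_state(self, state: str | None) -> pd.DataFrame:
        if state is None:
            return self.frame
        return self.frame.xs(state, level="state", drop_level=False)

    def state_labels(self) -> np.ndarray:
        return self.frame.index.get_level_values("state").to_numpy()

    def mouse_ids(self) -> np.ndarray:
        return self.frame.index.get_level_values("mouse_id").to_numpy()


def to_feature_matrix(table: ConcentrationTable, scaling: str = "none") -> FeatureMatrix:
    """Pivot a fully imputed table to a wide observation-by-analyte matrix.

    Rows are ordered by (state, mouse, sample). Z-scoring pools both states
    (column mean/SD over all rows) so state signal stays in the features; a
    zero-SD column is an error naming the analyte.
    """
    if scaling not in ("none", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}; use 'none' or 'zscore'")
    if not table.is_complete():
        raise ValidationError("feature matrix requires a fully imputed table")
    wide = table.df.pivot_table(
        index=["mouse_id", "state", "sample_index"],
        columns="analyte",
        values="concentration_nM",
        aggfunc="first",
    )
    wide = wide.reindex(columns=list(table.panel))
    if wide.isna().any().any():
        raise ValidationError("panel is incomplete for some (mouse, sample) rows")
    wide = wide.sort_index(level=["state", "mouse_id", "sample_index"])
    wide.columns.name = None
    if scaling == "zscore":
        sd = wide.std(axis=0, ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValidationError(f"cannot z-score constant column: {zero.index[0]}")
        wide = (wide - wide.mean(axis=0)) / sd
    return FeatureMatrix(wide, scaling)


def per_mouse_means(table: ConcentrationTable) -> pd.DataFrame:
    """Per-(mouse, analyte) mean concentration over the available samples.

    This is the per-mouse average of the sequential dialysis samples, the
    quantity group summaries are computed from.
    """
    if not table.is_complete():
        raise ValidationError("per-mouse means require a fully imputed table")
    out = (
        table.df.groupby(["mouse_id", "state", "analyte"], sort=True)["concentration_nM"]
        .mean()
        .unstack("analyte")
        .reindex(columns=list(table.panel))
    )
    out.columns.name = None
    return out
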