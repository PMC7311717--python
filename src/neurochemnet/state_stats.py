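"""State-effect testing for two-state microdialysis panels.

The design is completely randomized with subsampling: five sequential
dialysis samples per mouse, with the mouse (not the sample) as the unit of
replication. Each analyte is rank-transformed across all observations of
both states and tested with a nested mixed-model ANOVA in which the state
effect is judged against mouse-within-state variance, giving df = (1,
n_mice - 2). Raw p-values are Benjamini-Hochberg adjusted across the
panel; Fisher's LSD provides the post hoc wake-vs-anesthesia comparison on
per-mouse mean ranks. Time trends are compared between states by an
ordinary least-squares two-line model, and probe placement is compared by
an unpaired t test on the 3-D Euclidean position of each dialysis site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import ConcentrationTable, ValidationError
from .preprocess import rank_transform

__all__ = [
    "StateTestResult",
    "LSDResult",
    "SlopeTest",
    "ProbeTestResult",
    "nested_rank_anova",
    "bh_adjust",
    "fisher_lsd",
    "compare_slopes",
    "probe_site_test",
    "t_to_p",
    "run_state_tests",
    "StateEffectModel",
    "StateEffectResults",
]


@dataclass
class StateTestResult:
    analyte: str
    F: float
    df_num: int
    df_den: int
    p_raw: float
    mean_rank_wake: float
    mean_rank_iso: float
    p_fdr: float | None = None
    lsd_significant: bool | None = None

    @property
    def direction(self) -> int:
        """Sign of (iso mean rank - wake mean rank): +1 higher under
        anesthesia, -1 lower, 0 tied."""
        return int(np.sign(self.mean_rank_iso - self.mean_rank_wake))


@dataclass
class LSDResult:
    analyte: str
    lsd: float
    mean_rank_diff: float
    significant: bool


@dataclass
class SlopeTest:
    analyte: str
    slope_wake: float
    slope_iso: float
    se_diff: float
    t: float
    df: int
    p: float

    @property
    def diff(self) -> float:
        return self.slope_iso - self.slope_wake


@dataclass
class ProbeTestResult:
    group_mean_mm: dict[str, np.ndarray]
    scalars: dict[str, np.ndarray]
    t: float
    df: int
    p: float
    reference: str = "bregma"


def _analyte_frame(table: ConcentrationTable, analyte: str) -> pd.DataFrame:
    if analyte not in table.panel:
        raise ValidationError(f"analyte {analyte!r} not in panel")
    sub = table.df[table.df["analyte"] == analyte]
    if sub["concentration_nM"].isna().any():
        raise ValidationError("state tests require a fully imputed table")
    return sub


def nested_rank_anova(table: ConcentrationTable, analyte: str) -> StateTestResult:
    """Mixed-model ANOVA on ranks for one analyte.

    All observations of the analyte (both states) are mid-ranked. The
    state sum of squares is computed from state mean ranks and the error
    term from per-mouse mean ranks weighted by sample count (the standard
    nested decomposition, exact for balanced designs and the documented
    weighted-mean approximation otherwise):

        F = [sum_g N_g (Rbar_g - Rbar)^2] /
            [sum_m n_m (Rbar_m - Rbar_g(m))^2 / (n_mice - 2)]

    with df = (1, n_mice - 2) and p from the F distribution.
    """
    sub = _analyte_frame(table, analyte)
    ranks = rank_transform(sub["concentration_nM"].to_numpy())
    frame = pd.DataFrame(
        {"mouse": sub["mouse_id"].to_numpy(), "state": sub["state"].to_numpy(), "rank": ranks}
    )
    mice = frame.groupby(["state", "mouse"])["rank"].agg(["mean", "count"])
    n_mice_per_state = mice.groupby(level="state").size()
    for state in ("wake", "iso"):
        if n_mice_per_state.get(state, 0) < 2:
            raise ValidationError(
                f"state {state!r} has fewer than 2 mice; no denominator degrees of freedom"
            )

    grand = frame["rank"].mean()
    state_stats_ = frame.groupby("state")["rank"].agg(["mean", "count"])
    ss_state = float((state_stats_["count"] * (state_stats_["mean"] - grand) ** 2).sum())
    state_mean = state_stats_["mean"]
    dev = mice["mean"] - state_mean.reindex(mice.index.get_level_values("state")).to_numpy()
    ss_mouse = float((mice["count"] * dev**2).sum())

    n_mice = len(mice)
    df_num, df_den = 1, n_mice - 2
    if ss_mouse > 0:
        f_stat = (ss_state / df_num) / (ss_mouse / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    elif ss_state > 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat, p = 0.0, 1.0
    return StateTestResult(
        analyte=analyte,
        F=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_raw=p,
        mean_rank_wake=float(state_mean["wake"]),
        mean_rank_iso=float(state_mean["iso"]),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_lsd(
    table: ConcentrationTable, analyte: str, anova: StateTestResult, alpha: float = 0.05
) -> LSDResult:
    """Fisher's least significant difference on per-mouse mean ranks.

    With two groups this reduces to an unpaired t test at level ``alpha``
    on the per-mouse mean ranks: LSD = t_{1-alpha/2, df} * sqrt(MS_mouse *
    (1/n_wake + 1/n_iso)) with MS_mouse the pooled variance of per-mouse
    mean ranks around their state means.
    """
    sub = _analyte_frame(table, analyte)
    ranks = rank_transform(sub["concentration_nM"].to_numpy())
    frame = pd.DataFrame(
        {"mouse": sub["mouse_id"].to_numpy(), "state": sub["state"].to_numpy(), "rank": ranks}
    )
    mouse_means = frame.groupby(["state", "mouse"])["rank"].mean()
    group_means = mouse_means.groupby(level="state").mean()
    n_by_state = mouse_means.groupby(level="state").size()
    dev = mouse_means - group_means.reindex(mouse_means.index.get_level_values("state")).to_numpy()
    df_den = int(len(mouse_means) - 2)
    ms_mouse = float((dev**2).sum()) / df_den
    lsd = float(
        stats.t.ppf(1 - alpha / 2, df_den)
        * np.sqrt(ms_mouse * (1.0 / n_by_state["wake"] + 1.0 / n_by_state["iso"]))
    )
    diff = float(group_means["iso"] - group_means["wake"])
    return LSDResult(analyte=analyte, lsd=lsd, mean_rank_diff=diff, significant=abs(diff) > lsd)


def compare_slopes(table: ConcentrationTable, analyte: str) -> SlopeTest:
    """Compare within-state time trends by a pooled two-line OLS model.

    Concentration is regressed on sample index separately per state (mice
    pooled, two intercepts + two slopes); the slope difference is the
    interaction term, tested with the pooled residual variance on
    N - 4 degrees of freedom.
    """
    sub = _analyte_frame(table, analyte)
    for state in ("wake", "iso"):
        if sub.loc[sub["state"] == state, "sample_index"].nunique() < 2:
            raise ValidationError(f"state {state!r} needs >= 2 distinct sample indices")
    y = sub["concentration_nM"].to_numpy(float)
    t = sub["sample_index"].to_numpy(float)
    iso = (sub["state"] == "iso").to_numpy(float)
    X = np.column_stack([np.ones_like(t), iso, t, iso * t])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise ValidationError("singular design in slope comparison")
    resid = y - X @ beta
    df = len(y) - 4
    mse = float(resid @ resid) / df
    cov = mse * np.linalg.inv(X.T @ X)
    slope_wake = float(beta[2])
    slope_iso = float(beta[2] + beta[3])
    diff = float(beta[3])
    se_diff = float(np.sqrt(cov[3, 3]))
    scale = float(np.mean(y**2)) or 1.0
    if mse <= 1e-24 * scale:  # noise-free fit: no residual variance
        t_stat = 0.0 if abs(diff) <= 1e-9 * max(1.0, abs(slope_wake)) else float("inf")
        p = 1.0 if t_stat == 0.0 else 0.0
    else:
        t_stat = diff / se_diff
        p = t_to_p(t_stat, df)
    return SlopeTest(
        analyte=analyte, slope_wake=slope_wake, slope_iso=slope_iso,
        se_diff=se_diff, t=float(t_stat), df=df, p=float(p),
    )


def t_to_p(t: float, df: int) -> float:
    """Two-tailed p for a t statistic on ``df`` degrees of freedom."""
    return float(2.0 * stats.t.sf(abs(t), df))


def probe_site_test(
    sites: pd.DataFrame,
    reference: str = "bregma",
    target_mm: tuple[float, float, float] = (3.0, 1.6, 2.0),
) -> ProbeTestResult:
    """Unpaired two-tailed t test on per-mouse 3-D Euclidean probe position.

    Each mouse's dialysis site is reduced to the Euclidean norm of its
    (AP, ML, DV) coordinates relative to bregma (``reference="bregma"``) or
    to the stereotaxic target (``reference="target"``); states are compared
    with the pooled-variance t test, df = n_wake + n_iso - 2.
    """
    if reference == "bregma":
        ref = np.zeros(3)
    elif reference == "target":
        ref = np.asarray(target_mm, dtype=float)
    else:
        raise ValueError(f"unknown reference {reference!r}; use 'bregma' or 'target'")
    coords = {}
    scalars = {}
    for state in ("wake", "iso"):
        sub = sites[sites["state"] == state][["ap_mm", "ml_mm", "dv_mm"]].to_numpy(float)
        if len(sub) < 2:
            raise ValidationError(f"state {state!r} needs >= 2 probe sites")
        coords[state] = sub.mean(axis=0)
        scalars[state] = np.linalg.norm(sub - ref, axis=1)
    res = stats.ttest_ind(scalars["wake"], scalars["iso"], equal_var=True)
    df = len(scalars["wake"]) + len(scalars["iso"]) - 2
    t_stat = float(res.statistic)
    if np.isnan(t_stat):  # zero pooled variance and equal means
        t_stat, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    return ProbeTestResult(
        group_mean_mm=coords, scalars=scalars, t=t_stat, df=df, p=p, reference=reference
    )


def run_state_tests(table: ConcentrationTable) -> list[StateTestResult]:
    """Nested rank ANOVA for every panel analyte, BH-adjusted jointly."""
    results = [nested_rank_anova(table, a) for a in table.panel]
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, p in zip(results, adjusted):
        r.p_fdr = float(p)
        r.lsd_significant = fisher_lsd(table, r.analyte, r).significant
    return results


class StateEffectModel:
    """Per-analyte state-effect model for a fully imputed table.

    ``fit()`` runs the rank nested ANOVA across the panel with joint BH
    adjustment, the LSD post hoc, and the per-analyte slope comparison,
    returning a :class:`StateEffectResults`.
    """

    def __init__(self, table: ConcentrationTable):
        if not table.is_complete():
            raise ValidationError(
                "StateEffectModel requires an imputed table; run impute_lloq first"
            )
        self.table = table

    def fit(self) -> "StateEffectResults":
        tests = run_state_tests(self.table)
        slopes = [compare_slopes(self.table, a) for a in self.table.panel]
        return StateEffectResults(self.table, tests, slopes)


class StateEffectResults:
    """Fitted state-effect results with a summary table."""

    def __init__(self, table, tests: list[StateTestResult], slopes: list[SlopeTest]):
        self.table = table
        self.tests = tests
        self.slopes = slopes

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, s in zip(self.tests, self.slopes):
            rows.append(
                {
                    "analyte": r.analyte,
                    "F": r.F,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr,
                    "direction": r.direction,
                    "lsd_significant": r.lsd_significant,
                    "slope_wake": s.slope_wake,
                    "slope_iso": s.slope_iso,
                    "slope_diff_p": s.p,
                }
            )
        return pd.DataFrame(rows).set_index("analyte")

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [r.analyte for r in self.tests if (r.p_fdr or 1.0) < alpha]

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "State effect on neurotransmitter concentration (rank nested ANOVA)",
            f"design: {self.table.design[0]} wake + {self.table.design[1]} iso mice, "
            f"{self.table.design[2]} samples/mouse; error term: mouse within state",
            "",
            frame.to_string(float_format=lambda x: f"{x:.4g}"),
            "",
            "direction: +1 = higher under isoflurane, -1 = lower; "
            "p_fdr: Benjamini-Hochberg across the panel",
        ]
        return "\n".join(lines)
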