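"""Small matplotlib helpers for the standard figures of this analysis:
per-state concentration distributions and per-analyte time courses."""

from __future__ import annotations

import numpy as np

from .panel import ConcentrationTable
from .preprocess import per_mouse_means

STATE_COLORS = {"wake": "#2b6cb0", "iso": "#c53030"}


def plot_concentration_boxes(table: ConcentrationTable, axes=None):
    """Box plots of per-mouse mean concentrations, one panel per analyte,
    wake vs. isoflurane side by side."""
    import matplotlib.pyplot as plt

    means = per_mouse_means(table)
    analytes = list(table.panel)
    if axes is None:
        fig, axes = plt.subplots(2, int(np.ceil(len(analytes) / 2)), figsize=(14, 6))
        axes = np.ravel(axes)
    for ax, analyte in zip(np.ravel(axes), analytes):
        data = [
            means.xs(state, level="state")[analyte].dropna().to_numpy()
            for state in ("wake", "iso")
        ]
        bp = ax.boxplot(data, tick_labels=["wake", "iso"], patch_artist=True, showmeans=True)
        for patch, state in zip(bp["boxes"], ("wake", "iso")):
            patch.set_facecolor(STATE_COLORS[state])
            patch.set_alpha(0.5)
        ax.set_title(analyte)
        ax.set_ylabel("nM")
    return np.ravel(axes)


def plot_time_course(table: ConcentrationTable, analyte: str, ax=None):
    """Median and interquartile range per sample interval, by state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = table.df[table.df["analyte"] == analyte].dropna(subset=["concentration_nM"])
    for state in ("wake", "iso"):
        sub = df[df["state"] == state]
        grouped = sub.groupby("sample_index")["concentration_nM"]
        med = grouped.median()
        q1, q3 = grouped.quantile(0.25), grouped.quantile(0.75)
        ax.errorbar(
            med.index, med.to_numpy(),
            yerr=np.vstack([(med - q1).to_numpy(), (q3 - med).to_numpy()]),
            label=state, color=STATE_COLORS[state], marker="o", capsize=3,
        )
    ax.set_xlabel("dialysis sample")
    ax.set_ylabel(f"{analyte} (nM)")
    ax.legend()
    return ax
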