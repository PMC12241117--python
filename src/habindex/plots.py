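"""Figure analogues: index trajectories per habitat and trend marginal means."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .weighting import METHODS

__all__ = ["plot_index_series", "plot_trend_emmeans"]

_METHOD_COLORS = dict(zip(METHODS, ("black", "tab:blue", "tab:orange", "tab:red")))


def plot_index_series(index: pd.DataFrame, path, gsd_bars: bool = True):
    """One panel per habitat: Distribution Index through time by method.

    Vertical bars show the geometric standard deviation (the index
    multiplied/divided by the gsd), drawn for the unweighted series only
    to keep panels readable.
    """
    habitats = sorted(index["habitat"].unique())
    ncol = min(5, len(habitats))
    nrow = int(np.ceil(len(habitats) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), sharex=True, squeeze=False
    )
    for ax, habitat in zip(axes.flat, habitats):
        sub = index[index["habitat"] == habitat]
        for method in [m for m in METHODS if m in set(sub["method"])]:
            s = sub[sub["method"] == method].sort_values("year")
            ax.plot(
                s["year"], s["di"], label=method,
                color=_METHOD_COLORS.get(method), lw=1.2,
            )
            if gsd_bars and method == "Unw":
                ax.vlines(
                    s["year"], s["di"] / s["gsd"], s["di"] * s["gsd"],
                    color="grey", lw=0.4, alpha=0.5,
                )
        ax.set_title(f"habitat {habitat}", fontsize=9)
    for ax in axes.flat[len(habitats):]:
        ax.set_visible(False)
    axes.flat[0].legend(fontsize=7)
    fig.supylabel("Distribution Index")
    fig.supxlabel("year")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_trend_emmeans(emmeans: pd.DataFrame, path, period: str | None = None):
    """Marginal mean trend per habitat x method with 95% CI bars."""
    df = emmeans
    if period is not None and "period" in df.columns:
        df = df[df["period"] == period]
    habitats = sorted(df["habitat"].unique())
    methods = [m for m in METHODS if m in set(df["method"])]
    fig, ax = plt.subplots(figsize=(1.1 * len(habitats) + 2, 4))
    width = 0.8 / max(len(methods), 1)
    for k, method in enumerate(methods):
        sub = df[df["method"] == method].set_index("habitat")
        x = np.array(
            [habitats.index(h) + (k - (len(methods) - 1) / 2) * width
             for h in sub.index]
        )
        ax.errorbar(
            x, sub["mean"],
            yerr=[sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]],
            fmt="o", ms=4, capsize=2, label=method,
            color=_METHOD_COLORS.get(method),
        )
    ax.axhline(0, color="grey", lw=0.8, ls=":")
    ax.set_xticks(range(len(habitats)), habitats)
    ax.set_xlabel("habitat")
    ax.set_ylabel("mean trend (proportional change / yr)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
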