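"""Thin matplotlib layer over the tabular outputs: forest and QQ plots."""

from __future__ import annotations

import numpy as np


def forest_plot(result, ax=None):
    """Forest plot of one pooled result: per-study effects with 95% CIs and
    normalized weights, plus the pooled estimate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * result.k + 2))
    frame = result.forest_frame()
    ys = np.arange(len(frame))[::-1]
    ax.errorbar(
        frame["y"], ys,
        xerr=[frame["y"] - frame["ci_low"], frame["ci_high"] - frame["y"]],
        fmt="*", color="tab:red", ecolor="tab:blue", capsize=3,
    )
    for yi, w in zip(ys, frame["normalized_weight"]):
        ax.annotate(f"w={w:.2f}", (ax.get_xlim()[1], yi), fontsize=8,
                    ha="right")
    ax.axvline(result.pooled_lfc, color="gray", linestyle="--",
               label=f"pooled LFC {result.pooled_lfc:+.2f}")
    ax.axvline(0.0, color="black", linewidth=0.5)
    ax.set_yticks(ys)
    ax.set_yticklabels(frame["study_id"])
    ax.set_xlabel("log2 fold change")
    ax.set_title(f"{result.gene} ({result.analysis}, {result.model})")
    ax.legend(loc="best", fontsize=8)
    return ax


def qq_plot(qq_table, ax=None, title: str = ""):
    """QQ plot of observed z-scores against standard-normal quantiles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(qq_table["theoretical"], qq_table["observed"], ".", ms=3)
    lim = [qq_table.min().min(), qq_table.max().max()]
    ax.plot(lim, lim, color="tab:red", linewidth=1)
    ax.set_xlabel("theoretical N(0,1) quantile")
    ax.set_ylabel("observed z")
    if title:
        ax.set_title(title)
    return ax
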