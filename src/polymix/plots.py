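"""Plotting helpers: prevalence-by-percentile curve and tail-shaded densities."""

from __future__ import annotations

import numpy as np

from polymix.strata import PercentileTable, TailResult


def plot_prevalence_curve(table: PercentileTable, path, color: str = "darkred",
                          title: str | None = None) -> None:
    """Disease prevalence with 95% CI across the 100 score percentile groups.

    Dotted lines mark the prevalence in the lowest and highest percentiles.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.table
    fig, ax = plt.subplots(figsize=(7, 4))
    yerr = np.vstack([t["prevalence"] - t["ci_low"], t["ci_high"] - t["prevalence"]])
    ax.errorbar(t["percentile"], t["prevalence"], yerr=yerr, fmt="o",
                ms=3, color=color, ecolor="lightgray", capsize=0)
    for p in (t["prevalence"].iloc[0], t["prevalence"].iloc[-1]):
        ax.axhline(p, ls=":", lw=1, color="gray")
    ax.set_xlabel("PGS percentile")
    ax.set_ylabel("Prevalence")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tail_density(score, tails: list[TailResult], path,
                      title: str | None = None) -> None:
    """Score density with the middle quintile and found tail regions shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    score = np.asarray(score, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    counts, bins, _ = ax.hist(score, bins=100, density=True, color="lightsteelblue",
                              alpha=0.9)
    q40, q60 = np.percentile(score, [40, 60])
    ax.axvspan(q40, q60, color="gray", alpha=0.3, label="middle quintile")
    shades = iter(["#f4a582", "#d6604d", "#b2182b", "#67001f"])
    for res in tails:
        if not res.found:
            continue
        shade = next(shades, "#67001f")
        if res.side == "upper":
            x0 = np.percentile(score, 100.0 - res.cut_percentile)
            ax.axvspan(x0, score.max(), color=shade, alpha=0.4,
                       label=f"{res.side} >= {res.fold_threshold:g}-fold "
                             f"({res.proportion_of_population:.1f}%)")
        else:
            x1 = np.percentile(score, res.cut_percentile)
            ax.axvspan(score.min(), x1, color=shade, alpha=0.4,
                       label=f"{res.side} <= {res.fold_threshold:g}-fold "
                             f"({res.proportion_of_population:.1f}%)")
    ax.set_xlabel("Polygenic score")
    ax.set_ylabel("Density")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
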