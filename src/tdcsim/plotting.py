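"""Summary figures for a study report (descriptive-statistics boxes, CV bars)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_tissue_stats", "plot_variability"]


def plot_tissue_stats(report, montage: str):
    """Box-style chart of |E| statistics per tissue, one panel per model.

    Boxes span the interquartile range with the median marked; whiskers run
    from the minimum to the maximum of the within-tissue distribution.
    """
    df = report.tissue_stats[report.tissue_stats.montage == montage]
    models = sorted(df.model.unique())
    fig, axes = plt.subplots(1, len(models), figsize=(4 * len(models), 3.2),
                             sharey=True, squeeze=False)
    for ax, model in zip(axes[0], models):
        sub = df[df.model == model]
        boxes = [
            {"label": r["tissue"].replace("brain_", "").replace("_", " "),
             "med": r["median"], "q1": r["q25"], "q3": r["q75"],
             "whislo": r["min"], "whishi": r["max"], "fliers": []}
            for _, r in sub.iterrows()
        ]
        ax.bxp(boxes, showfliers=False)
        ax.set_title(model)
        ax.tick_params(axis="x", rotation=60)
    axes[0][0].set_ylabel("|E| (V/m)")
    fig.suptitle(f"Montage {montage}")
    fig.tight_layout()
    return fig


def plot_variability(report):
    """Grouped bars of the CV (dB) of peak and median |E| per montage/tissue."""
    df = report.variability
    montages = sorted(df.montage.unique())
    fig, axes = plt.subplots(1, len(montages), figsize=(4 * len(montages), 3.2),
                             sharey=True, squeeze=False)
    for ax, m in zip(axes[0], montages):
        sub = df[df.montage == m].pivot(index="tissue", columns="statistic", values="cv_db")
        sub.plot.bar(ax=ax, legend=(m == montages[0]))
        ax.set_title(f"Montage {m}")
        ax.set_xlabel("")
    axes[0][0].set_ylabel("CV (dB)")
    fig.tight_layout()
    return fig
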