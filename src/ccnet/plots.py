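"""Simple metric-vs-density visualisation of group profiles."""

from __future__ import annotations

import pandas as pd

from .metrics import GLOBAL_METRICS, MetricTable


def plot_metric_profiles(ztable: MetricTable, groups: pd.Series, ax=None):
    """Mean z-standardised metric per group across the density grid.

    One panel per metric, group means with +-1 SEM bands; returns the
    matplotlib figure.
    """
    import matplotlib.pyplot as plt

    df = ztable.data
    g = groups.loc[df.index]
    fig, axes = plt.subplots(1, len(GLOBAL_METRICS), figsize=(12, 3.5), sharey=True)
    for ax_, metric in zip(axes, GLOBAL_METRICS):
        sub = df[metric]
        for label in sorted(g.unique()):
            block = sub[g == label]
            mean = block.mean()
            sem = block.std(ddof=1) / (len(block) ** 0.5)
            ax_.plot(mean.index, mean.values, marker="o", label=label)
            ax_.fill_between(mean.index, mean - sem, mean + sem, alpha=0.25)
        ax_.set_title(metric)
        ax_.set_xlabel("density")
    axes[0].set_ylabel("z score")
    axes[0].legend()
    fig.tight_layout()
    return fig
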