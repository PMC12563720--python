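"""Figure export: loadings heatmap and time-varying effect bands."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_loadings_heatmap", "plot_effect_trajectories"]


def plot_loadings_heatmap(loadings, metabolite_names, path=None, ax=None):
    """Heatmap of posterior-mean factor loadings (exposures x factors)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    loadings = np.asarray(loadings)
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 0.5 * len(metabolite_names) + 1.5))
    else:
        fig = ax.figure
    vmax = np.abs(loadings).max() or 1.0
    im = ax.imshow(loadings, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(metabolite_names)), metabolite_names)
    ax.set_xticks(range(loadings.shape[1]),
                  [f"factor {k + 1}" for k in range(loadings.shape[1])])
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("posterior-mean loadings")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_effect_trajectories(summary, path=None):
    """Per-(outcome, factor) trajectories with credible bands.

    ``summary`` is an :class:`~bmfr.postprocess.EffectSummary`; the layout
    is a grid of outcomes (rows) by factors (columns), each panel showing
    the posterior-mean effect over age with the equal-tailed band.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    q, K, T = summary.factor_mean.shape
    onames = summary.outcome_names or [f"y{j}" for j in range(q)]
    fig, axes = plt.subplots(
        q, K, figsize=(3.0 * K, 2.2 * q), sharex=True, squeeze=False
    )
    for j in range(q):
        for k in range(K):
            ax = axes[j][k]
            ax.fill_between(
                summary.times, summary.factor_lo[j, k], summary.factor_hi[j, k],
                alpha=0.3, color="tab:blue", linewidth=0,
            )
            ax.plot(summary.times, summary.factor_mean[j, k], color="black")
            ax.axhline(0.0, color="gray", linewidth=0.6, linestyle=":")
            if j == 0:
                ax.set_title(f"factor {k + 1}")
            if k == 0:
                ax.set_ylabel(onames[j])
            if j == q - 1:
                ax.set_xlabel("age (years)")
    fig.suptitle(f"time-varying factor effects ({summary.level:.0%} bands)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
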