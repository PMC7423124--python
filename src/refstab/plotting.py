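"""Convenience figures: M bar chart, V bar chart, fold-change profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .genorm import GeNormResults, PairwiseVariationSeries  # noqa: E402
from .relquant import ExpressionProfile  # noqa: E402

__all__ = ["plot_m_values", "plot_v_series", "plot_profiles"]


def plot_m_values(results: GeNormResults, ax=None):
    """Genes ordered least to most stable vs their geNorm M."""
    ax = ax or plt.subplots(figsize=(7, 4))[1]
    order = results.gene_order[::-1]
    ax.bar(order, results.m_final.loc[order], color="steelblue")
    ax.axhline(1.5, color="firebrick", ls="--", lw=1, label="M = 1.5")
    ax.set_ylabel("geNorm M")
    ax.tick_params(axis="x", rotation=60)
    ax.legend()
    return ax


def plot_v_series(series: PairwiseVariationSeries, cutoff: float = 0.15, ax=None):
    ax = ax or plt.subplots(figsize=(6, 4))[1]
    labels = [f"V{n}/{n + 1}" for n in series.values.index]
    ax.bar(labels, series.values.to_numpy(), color="darkseagreen")
    ax.axhline(cutoff, color="firebrick", ls="--", lw=1, label=f"cut-off {cutoff}")
    ax.set_ylabel("pairwise variation V")
    ax.legend()
    return ax


def plot_profiles(profiles: dict[str, ExpressionProfile], ax=None):
    """Mean +/- SD fold-change per strategy across timepoints."""
    ax = ax or plt.subplots(figsize=(7, 4))[1]
    for label, prof in profiles.items():
        fc = prof.fold_change
        ax.errorbar(fc.index, fc["mean"], yerr=fc["sd"], marker="o",
                    capsize=3, label=label)
    ax.axhline(1.0, color="gray", lw=0.8)
    ax.set_xlabel("timepoint")
    ax.set_ylabel("fold change vs control")
    ax.legend(fontsize=8)
    return ax
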