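"""BestKeeper descriptive reference-gene stability.

BestKeeper works directly on raw Cq. Each candidate gene is summarised by
its Cq dispersion — by default the mean absolute deviation from the
arithmetic mean (the original tool's "SD"), optionally the n-1 standard
deviation — and the coefficient of variation CV = dispersion / mean * 100.
Genes with dispersion below 1 cycle are conventionally considered stable.
The BestKeeper index is the per-sample geometric mean of the Cq of the
stable candidates, and each gene is additionally characterised by its
Pearson correlation with that index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CqTable, collapse_replicates

__all__ = ["BestKeeper", "BestKeeperResults", "stability_rule_sd"]


@dataclass
class BestKeeperResults:
    """Per-gene descriptive statistics and the per-sample BestKeeper index."""

    per_gene: pd.DataFrame     # mean, geo_mean, min, max, sd, cv, r, p_value
    index: pd.Series           # per-sample geometric mean Cq of stable genes
    index_genes: list[str]     # genes entering the index (dispersion < 1)
    dispersion_mode: Literal["mad", "sd"]
    warnings_: list[str]

    def summary(self) -> pd.DataFrame:
        return self.per_gene.sort_values("cv")

    def cv_ranks(self) -> pd.Series:
        """Ordinal ranks by CV (lowest CV = rank 1, ties by gene name)."""
        cv = self.per_gene["cv"]
        order = sorted(cv.index, key=lambda g: (cv[g], g))
        return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").loc[
            cv.index
        ]


class BestKeeper:
    """BestKeeper stability model over a Cq table.

    Parameters
    ----------
    table : CqTable
        Raw Cq values; replicates are collapsed (mean) before analysis
        unless ``collapse=False``.
    dispersion : {"mad", "sd"}
        "mad" = mean absolute deviation from the arithmetic mean (the
        original tool's convention), "sd" = n-1 standard deviation.
    """

    def __init__(
        self,
        table: CqTable,
        dispersion: Literal["mad", "sd"] = "mad",
        collapse: bool = True,
        sd_threshold: float = 1.0,
    ):
        if dispersion not in ("mad", "sd"):
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
        self.table = collapse_replicates(table) if collapse else table
        self.dispersion = dispersion
        self.sd_threshold = sd_threshold

    def fit(self) -> BestKeeperResults:
        cq = self.table.cq
        if cq.shape[1] < 2:
            raise ValueError("BestKeeper needs >= 2 samples per gene")
        warnings_: list[str] = []
        mean = cq.mean(axis=1)
        if self.dispersion == "mad":
            disp = (cq.sub(mean, axis=0)).abs().mean(axis=1)
        else:
            disp = cq.std(axis=1, ddof=1)
        stats_df = pd.DataFrame(
            {
                "mean": mean,
                "geo_mean": np.exp(np.log(cq).mean(axis=1)),
                "min": cq.min(axis=1),
                "max": cq.max(axis=1),
                "sd": disp,
                "cv": disp / mean * 100.0,
            }
        )
        stable = list(stats_df.index[stats_df["sd"] < self.sd_threshold])
        if not stable:
            warnings_.append(
                f"no gene passes the SD < {self.sd_threshold:g} rule; "
                "index computed over all genes"
            )
            index_genes = list(stats_df.index)
        else:
            index_genes = stable
        index = np.exp(np.log(cq.loc[index_genes]).mean(axis=0))
        index.name = "bestkeeper_index"

        r_vals, p_vals = {}, {}
        for g in cq.index:
            x = cq.loc[g].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(index.to_numpy())
            if mask.sum() < 2 or np.std(x[mask]) == 0 or np.std(index.to_numpy()[mask]) == 0:
                r_vals[g], p_vals[g] = np.nan, np.nan
                warnings_.append(f"correlation undefined for gene {g}")
                continue
            r, p = stats.pearsonr(x[mask], index.to_numpy()[mask])
            r_vals[g], p_vals[g] = float(r), float(p)
        stats_df["r"] = pd.Series(r_vals)
        stats_df["p_value"] = pd.Series(p_vals)
        return BestKeeperResults(
            per_gene=stats_df,
            index=index,
            index_genes=index_genes,
            dispersion_mode=self.dispersion,
            warnings_=warnings_,
        )


def stability_rule_sd(results: BestKeeperResults, threshold: float = 1.0) -> pd.Series:
    """Per-gene verdict of the strict ``dispersion < threshold`` rule."""
    return results.per_gene["sd"] < threshold
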