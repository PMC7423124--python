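"""Relative quantification of target genes against reference genes.

Fold-changes of a target gene at each treatment timepoint relative to the
untreated control are computed per biological replicate and summarised as
mean +/- SD. Two quantification rules are implemented:

* livak  -- 2^(-ddCq), ddCq = (Cq_target - Cq_ref)_treated
  - (Cq_target - Cq_ref)_control; assumes perfect doubling.
* pfaffl -- F_t^(dCq_target) / F_r^(dCq_ref) with dCq = control - treated
  and F the gene-specific amplification factors.

The reference side is a single gene, the arithmetic mean of several
reference genes' Cq (averaged-Cq rule), or — pfaffl only — the geometric
mean of per-reference ratios. A reference gene whose own expression drifts
under treatment biases every target fold-change; comparing strategies makes
that bias visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .cq_data import CqTable, EfficiencyMap

__all__ = [
    "NormalizationStrategy",
    "ExpressionProfile",
    "relative_expression",
    "peak_timepoint",
    "compare_strategies",
]


@dataclass(frozen=True)
class NormalizationStrategy:
    """A named choice of reference gene(s) for normalization."""

    name: Literal["single_rg", "multi_rg_avg_cq", "multi_rg_geomean"]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if self.name == "single_rg" and len(genes) != 1:
            raise ValueError("single_rg strategy takes exactly one gene")
        if self.name in ("multi_rg_avg_cq", "multi_rg_geomean") and len(genes) < 2:
            raise ValueError(f"{self.name} strategy needs >= 2 genes")

    @classmethod
    def single(cls, gene: str) -> "NormalizationStrategy":
        return cls("single_rg", (gene,))

    @classmethod
    def multi(cls, genes: Sequence[str], rule: str = "avg_cq") -> "NormalizationStrategy":
        return cls(f"multi_rg_{rule}", tuple(genes))  # type: ignore[arg-type]

    @property
    def label(self) -> str:
        return f"{self.name}({','.join(self.genes)})"


@dataclass
class ExpressionProfile:
    """Per-timepoint fold-change of one target under one strategy."""

    target: str
    strategy: NormalizationStrategy
    method: str
    fold_change: pd.DataFrame    # index timepoint; columns mean, sd, n_replicates
    per_replicate: pd.DataFrame  # timepoint x replicate fold-change ratios
    warnings_: list[str] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.fold_change["mean"]


def _ratio(
    cq_target_tr: float, cq_target_ct: float,
    rg_cq_tr: np.ndarray, rg_cq_ct: np.ndarray,
    factors_rg: np.ndarray, factor_t: float,
    strategy: NormalizationStrategy, method: str,
) -> float:
    d_target = cq_target_ct - cq_target_tr      # control - treated
    if method == "livak":
        # averaged-Cq pseudo-reference; base-2 throughout
        d_ref = rg_cq_ct.mean() - rg_cq_tr.mean()
        return float(2.0 ** (d_target - d_ref))
    if method != "pfaffl":
        raise ValueError(f"unknown method {method!r}")
    num = factor_t**d_target
    if strategy.name == "multi_rg_geomean":
        # geometric mean of single-reference pfaffl ratios
        ratios = num / factors_rg ** (rg_cq_ct - rg_cq_tr)
        return float(gmean(ratios))
    d_ref = rg_cq_ct.mean() - rg_cq_tr.mean()
    factor_ref = gmean(factors_rg)
    return float(num / factor_ref**d_ref)


def relative_expression(
    table: CqTable,
    target: str,
    strategy: NormalizationStrategy,
    eff: EfficiencyMap | None = None,
    method: Literal["livak", "pfaffl"] = "livak",
) -> ExpressionProfile:
    """Fold-change profile of ``target`` across timepoints vs the control.

    Replicates are paired control-vs-treated by replicate index; a replicate
    without a control sample is dropped with a warning. The control
    timepoint's fold-change is 1 by construction.
    """
    eff = eff or EfficiencyMap()
    missing = [g for g in (target, *strategy.genes) if g not in table.genes]
    if missing:
        raise KeyError(f"genes not in table: {missing}")
    controls = table.meta[table.meta["timepoint"] == 0]
    if controls.empty:
        raise ValueError("no control (timepoint 0) samples")
    warnings_: list[str] = []
    factors_rg = np.array([eff.factor(g) for g in strategy.genes])
    if (factors_rg <= 0).any() or eff.factor(target) <= 0:
        raise ValueError("efficiency factors must be positive")
    factor_t = eff.factor(target)

    ctrl_by_rep = {int(r): s for s, r in zip(controls.index, controls["replicate"])}
    rows: dict[float, dict[int, float]] = {}
    for sample, meta in table.meta.iterrows():
        rep = int(meta["replicate"])
        tp = float(meta["timepoint"])
        if rep not in ctrl_by_rep:
            warnings_.append(f"replicate {rep} has no control sample; dropped")
            continue
        ctrl = ctrl_by_rep[rep]
        vals_tr = table.cq.loc[[target, *strategy.genes], sample]
        vals_ct = table.cq.loc[[target, *strategy.genes], ctrl]
        if vals_tr.isna().any() or vals_ct.isna().any():
            warnings_.append(f"missing Cq for sample {sample}; replicate dropped")
            continue
        ratio = _ratio(
            float(vals_tr.iloc[0]), float(vals_ct.iloc[0]),
            vals_tr.iloc[1:].to_numpy(), vals_ct.iloc[1:].to_numpy(),
            factors_rg, factor_t, strategy, method,
        )
        rows.setdefault(tp, {})[rep] = ratio

    per_rep = pd.DataFrame(rows).T.sort_index()
    per_rep.index.name = "timepoint"
    fc = pd.DataFrame(
        {
            "mean": per_rep.mean(axis=1),
            "sd": per_rep.std(axis=1, ddof=1),
            "n_replicates": per_rep.notna().sum(axis=1),
        }
    )
    return ExpressionProfile(
        target=target, strategy=strategy, method=method,
        fold_change=fc, per_replicate=per_rep, warnings_=warnings_,
    )


def peak_timepoint(profile: ExpressionProfile) -> tuple[float, bool]:
    """Timepoint of maximal mean fold-change among non-control timepoints.

    Returns ``(timepoint, tied)``; ties break to the earliest timepoint.
    """
    means = profile.mean.drop(index=0.0, errors="ignore")
    if len(profile.mean) < 2 or len(means) < 1:
        raise ValueError("need >= 2 timepoints including a non-control one")
    peak = means.max()
    at_peak = sorted(means.index[means == peak])
    return float(at_peak[0]), len(at_peak) > 1


def compare_strategies(
    table: CqTable,
    target: str,
    strategies: Sequence[NormalizationStrategy],
    eff: EfficiencyMap | None = None,
    method: Literal["livak", "pfaffl"] = "livak",
) -> tuple[dict[str, ExpressionProfile], pd.DataFrame]:
    """Profiles per strategy plus per-timepoint divergence vs the multi-RG one.

    The baseline is the first multi-reference strategy (or the last strategy
    if none is multi). The divergence table holds each strategy's mean
    fold-change divided by the baseline's, and flags strategies whose peak
    timepoint differs from the baseline's.
    """
    if len(strategies) < 2:
        raise ValueError("need >= 2 strategies to compare")
    profiles = {
        s.label: relative_expression(table, target, s, eff, method) for s in strategies
    }
    baseline_strategy = next(
        (s for s in strategies if s.name.startswith("multi")), strategies[-1]
    )
    baseline = profiles[baseline_strategy.label]
    base_peak, _ = peak_timepoint(baseline)
    rows = {}
    peak_shifted = {}
    for label, prof in profiles.items():
        rows[label] = prof.mean / baseline.mean
        peak_shifted[label] = peak_timepoint(prof)[0] != base_peak
    divergence = pd.DataFrame(rows)
    divergence.attrs["baseline"] = baseline_strategy.label
    divergence.attrs["peak_shifted"] = peak_shifted
    return profiles, divergence
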