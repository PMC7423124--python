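"""Synthetic Cq experiments with known ground truth.

The generator emulates a cold-stress RT-qPCR study design: 12 candidate
reference genes measured over short (hours) or long (days) treatment
series with 3 biological replicates. Each gene's Cq is

    Cq(g, sample(tau, r)) = mu_g + drift_g(tau) - log_F(fold_g(tau))
                            + loading(tau, r) + eps,

with a per-sample loading term shared by all genes (Normal, SD lambda),
independent per-measurement noise (Normal, SD sigma_g), and fold-changes
entering through the gene's own amplification factor F so that
efficiency-corrected quantification recovers the designed fold-change
exactly in the noise-free limit. Drift models a gene whose expression
responds to the treatment (rising Cq = falling expression) — exactly what
a bad reference gene looks like.

Ground truth (role and parameters per gene) travels with every generated
table so tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .cq_data import CqTable

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_experiment",
    "generate_dilution_series",
    "short_preset",
    "long_preset",
]

#: candidate reference genes of the emulated study design
CANDIDATE_GENES = [
    "ACT", "TUB", "UBC", "EF1A", "GAPDH", "PP2A",
    "UBQ", "PGK", "RPS", "FBOX", "CYP", "GTPB",
]

SHORT_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)   # hours
LONG_TIMEPOINTS = (0.0, 1.0, 2.0, 4.0, 8.0)          # days

#: published Cq envelope the defaults are calibrated to
CQ_ENVELOPE = (16.6, 29.0)


@dataclass(frozen=True)
class GeneSpec:
    """One gene's generating parameters.

    role "stable": flat mean Cq. role "drifting": Cq rises by
    ``drift_per_step`` cycles per timepoint index (expression falls under
    treatment). role "target": expression follows ``fold_curve``
    (timepoint -> fold-change vs control), entering Cq through the gene's
    amplification factor.
    """

    name: str
    role: Literal["stable", "drifting", "target"] = "stable"
    baseline_cq: float | None = None      # drawn from the preset band if None
    sigma: float = 0.15                   # residual Cq noise, cycles
    drift_per_step: float = 0.0           # cycles per timepoint index
    fold_curve: Mapping[float, float] | None = None
    efficiency_factor: float = 2.0


@dataclass
class SyntheticSpec:
    """Full design of a synthetic Cq experiment."""

    genes: list[GeneSpec]
    timepoints: tuple[float, ...] = SHORT_TIMEPOINTS
    timepoint_unit: Literal["hours", "days"] = "hours"
    replicates: int = 3
    loading_sd: float = 0.3               # per-sample loading, cycles
    baseline_band: tuple[float, float] = (17.0, 26.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("field replicates must be >= 1")
        if self.loading_sd < 0:
            raise ValueError("field loading_sd must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("field genes contains duplicate names")
        for g in self.genes:
            if g.sigma < 0:
                raise ValueError(f"field sigma of gene {g.name} must be >= 0")
            if not 1.0 < g.efficiency_factor <= 2.2:
                raise ValueError(
                    f"field efficiency_factor of gene {g.name} out of (1, 2.2]"
                )
            if g.role == "target" and g.fold_curve is None:
                raise ValueError(f"field fold_curve required for target gene {g.name}")


@dataclass
class GroundTruth:
    """What the generator actually did, per gene."""

    roles: dict[str, str]
    baselines: dict[str, float]
    sigmas: dict[str, float]
    drifts: dict[str, float]
    fold_curves: dict[str, dict[float, float]]
    efficiency: dict[str, float]
    loading_sd: float
    seed: int

    def stable_genes(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == "stable"]

    def drifting_genes(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == "drifting"]

    def target_genes(self) -> list[str]:
        return [g for g, r in self.roles.items() if r == "target"]

    def reference_candidates(self) -> list[str]:
        return [g for g, r in self.roles.items() if r != "target"]

    def to_json(self) -> str:
        d = asdict(self)
        d["fold_curves"] = {
            g: {str(t): f for t, f in fc.items()} for g, fc in d["fold_curves"].items()
        }
        return json.dumps(d, indent=2)


def generate_experiment(spec: SyntheticSpec) -> tuple[CqTable, GroundTruth]:
    """Draw one Cq experiment; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    baselines: dict[str, float] = {}
    lo, hi = spec.baseline_band
    for g in spec.genes:
        if g.baseline_cq is not None:
            baselines[g.name] = float(g.baseline_cq)
        elif g.role == "drifting":
            # drifting genes accumulate cycles; keep them clear of the top
            baselines[g.name] = float(rng.uniform(lo + 1.0, min(hi, 24.0)))
        else:
            baselines[g.name] = float(rng.uniform(lo, hi))

    tps = sorted(spec.timepoints)
    sample_ids, meta_rows = [], []
    unit_tag = {"hours": "h", "days": "d"}[spec.timepoint_unit]
    for tp in tps:
        for r in range(1, spec.replicates + 1):
            sid = f"t{tp:g}{unit_tag}_r{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "timepoint": tp,
                 "timepoint_unit": spec.timepoint_unit, "group": None, "replicate": r}
            )
    loading = rng.normal(0.0, spec.loading_sd, size=len(sample_ids))

    values = np.empty((len(spec.genes), len(sample_ids)))
    for gi, g in enumerate(spec.genes):
        eps = rng.normal(0.0, g.sigma, size=len(sample_ids))
        for si, row in enumerate(meta_rows):
            tp = row["timepoint"]
            step = tps.index(tp)
            cq = baselines[g.name] + g.drift_per_step * step
            if g.fold_curve is not None:
                fold = float(g.fold_curve.get(tp, 1.0))
                cq -= np.log(fold) / np.log(g.efficiency_factor)
            values[gi, si] = cq + loading[si] + eps[si]

    cq_df = pd.DataFrame(values, index=[g.name for g in spec.genes], columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        roles={g.name: g.role for g in spec.genes},
        baselines=baselines,
        sigmas={g.name: g.sigma for g in spec.genes},
        drifts={g.name: g.drift_per_step for g in spec.genes},
        fold_curves={
            g.name: dict(g.fold_curve) for g in spec.genes if g.fold_curve is not None
        },
        efficiency={g.name: g.efficiency_factor for g in spec.genes},
        loading_sd=spec.loading_sd,
        seed=spec.seed,
    )
    return CqTable(cq_df, meta), truth


def generate_dilution_series(
    gene: str,
    factor: float,
    levels: int = 5,
    replicates: int = 3,
    noise_sd: float = 0.0,
    intercept: float = 22.0,
    seed: int = 0,
) -> list[tuple[str, float, float]]:
    """10-fold serial-dilution Cq series for one gene.

    Cq = intercept - log10(amount) / log10(factor) + noise, so a noise-free
    series refits to exactly the generating efficiency. Returns
    (gene, amount, cq) rows ready for :func:`refstab.efficiency.fit_dilution_table`.
    """
    if factor <= 1.0:
        raise ValueError("amplification factor must exceed 1")
    if levels < 3:
        raise ValueError("need >= 3 dilution levels")
    rng = np.random.default_rng(seed)
    rows = []
    for lvl in range(levels):
        amount = 10.0 ** (-lvl)
        for _ in range(replicates):
            cq = intercept - np.log10(amount) / np.log10(factor)
            cq += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((gene, amount, float(cq)))
    return rows


def _default_genes(
    timepoints: tuple[float, ...],
    drifting_gene: str = "PGK",
    drift_per_step: float = 0.4,
    sigma: float = 0.15,
    include_targets: bool = False,
    target_peak: float | None = None,
) -> list[GeneSpec]:
    genes = [
        GeneSpec(
            name=g,
            role="drifting" if g == drifting_gene else "stable",
            sigma=sigma,
            drift_per_step=drift_per_step if g == drifting_gene else 0.0,
        )
        for g in CANDIDATE_GENES
    ]
    if include_targets:
        peak = target_peak if target_peak is not None else sorted(timepoints)[2]
        curve = {
            tp: 1.0 + 5.0 * np.exp(-((np.log(tp / peak)) ** 2)) if tp > 0 else 1.0
            for tp in timepoints
        }
        genes.append(GeneSpec("HK3", role="target", sigma=sigma, fold_curve=curve))
        genes.append(
            GeneSpec("HKnull", role="target", sigma=sigma,
                     fold_curve={tp: 1.0 for tp in timepoints})
        )
    return genes


def short_preset(seed: int = 0, include_targets: bool = False) -> SyntheticSpec:
    """Short-period design: {0, 0.5, 1, 2, 4, 8} hours, 3 replicates.

    11 stable candidates (sigma 0.15) plus one drifting candidate
    (+0.4 cycles per timepoint step), loading SD 0.3. Optional targets: a
    peaked induction (peak at 1 h) and a null (unchanged) gene.
    """
    return SyntheticSpec(
        genes=_default_genes(SHORT_TIMEPOINTS, include_targets=include_targets,
                             target_peak=1.0),
        timepoints=SHORT_TIMEPOINTS,
        timepoint_unit="hours",
        seed=seed,
    )


def long_preset(seed: int = 0, include_targets: bool = False) -> SyntheticSpec:
    """Long-period design: {0, 1, 2, 4, 8} days, 3 replicates."""
    return SyntheticSpec(
        genes=_default_genes(LONG_TIMEPOINTS, include_targets=include_targets,
                             target_peak=4.0),
        timepoints=LONG_TIMEPOINTS,
        timepoint_unit="days",
        seed=seed,
    )


def write_experiment(
    table: CqTable, truth: GroundTruth, out_dir: str | Path, stem: str = "experiment"
) -> tuple[Path, Path]:
    """Write the long-layout CSV plus the ground-truth sidecar JSON."""
    from .cq_data import write_cq_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    truth_path = out_dir / f"{stem}.truth.json"
    write_cq_table(table, csv_path, layout="long")
    truth_path.write_text(truth.to_json())
    return csv_path, truth_path
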