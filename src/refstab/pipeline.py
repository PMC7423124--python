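"""End-to-end stability pipeline: the full reference-gene workflow.

Runs replicate collapse, the quantity transform, all three stability
analyses, the consensus ranking, and the V-series reference-gene-count
decision on one Cq table, producing a combined per-gene report table
(gene, geNorm M + rank, NormFinder value + rank, mean rank, BestKeeper
CV + SD), the V series, and the chosen reference-gene set. Outputs carry
the configuration hash and seed so reruns are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from .bestkeeper import BestKeeper
from .consensus import mean_rank
from .cq_data import (
    CqTable,
    EfficiencyMap,
    collapse_replicates,
    cq_to_quantity,
    read_cq_table,
)
from .genorm import GeNorm, choose_rg_count
from .normfinder import NormFinder

log = logging.getLogger("refstab")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and modes for the full pipeline (defaults = the
    conventional cut-offs: M acceptability 1.5, V cut-off 0.15,
    BestKeeper SD rule 1.0 cycle, efficiency band 90-110%)."""

    m_threshold: float = 1.5
    v_cutoff: float = 0.15
    sd_threshold: float = 1.0
    efficiency_band: tuple[float, float] = (90.0, 110.0)
    replicate_mode: Literal["collapse", "individual"] = "collapse"
    collapse_stat: Literal["mean", "median"] = "mean"
    dispersion: Literal["mad", "sd"] = "mad"
    normfinder_group_by: str | None = None
    include_bestkeeper_in_consensus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m_threshold", "v_cutoff", "sd_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    """Bundle of all pipeline outputs."""

    stability_table: pd.DataFrame
    v_series: pd.Series
    chosen_n: int
    chosen_genes: list[str]
    v_warned: bool
    config: PipelineConfig
    config_hash: str
    warnings_: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the report tables as CSV; every file carries the config hash."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={self.config_hash} seed={self.config.seed}\n"
        paths = {}
        for name, obj in (
            ("stability", self.stability_table),
            ("v_series", self.v_series.rename("V").to_frame()),
        ):
            p = out_dir / f"{name}.csv"
            with open(p, "w") as fh:
                fh.write(header)
                obj.to_csv(fh)
            paths[name] = p
        p = out_dir / "chosen_reference_genes.csv"
        with open(p, "w") as fh:
            fh.write(header)
            pd.DataFrame(
                {"gene": self.chosen_genes, "n": self.chosen_n,
                 "warned": self.v_warned}
            ).to_csv(fh, index=False)
        paths["chosen"] = p
        return paths


def run_pipeline(
    source: str | Path | CqTable,
    config: PipelineConfig | None = None,
    eff: EfficiencyMap | None = None,
    layout: Literal["long", "wide"] = "long",
) -> PipelineReport:
    """Run the full stability workflow on a Cq CSV path or CqTable."""
    config = config or PipelineConfig()
    warnings_: list[str] = []

    if isinstance(source, CqTable):
        table = source
    else:
        try:
            table = read_cq_table(source, layout=layout)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError("read_cq_table", str(exc)) from exc
    if len(table.genes) < 2 or len(table.samples) < 2:
        raise PipelineError("read_cq_table", "need >= 2 genes and >= 2 samples")
    warnings_.extend(table.warnings_)

    try:
        analysed = (
            collapse_replicates(table, config.collapse_stat)
            if config.replicate_mode == "collapse"
            else table
        )
    except Exception as exc:
        raise PipelineError("collapse_replicates", str(exc)) from exc

    try:
        q = cq_to_quantity(analysed, eff)
    except Exception as exc:
        raise PipelineError("cq_to_quantity", str(exc)) from exc

    try:
        genorm_res = GeNorm(q).fit()
    except Exception as exc:
        raise PipelineError("genorm", str(exc)) from exc
    over = genorm_res.m_final[genorm_res.m_final >= config.m_threshold]
    if len(over):
        warnings_.append(
            f"genes exceed the M < {config.m_threshold:g} acceptability bound: "
            f"{sorted(over.index)}"
        )

    try:
        groups = (
            analysed.meta[config.normfinder_group_by]
            if config.normfinder_group_by
            else None
        )
        nf_res = NormFinder(q, groups=groups).fit()
    except Exception as exc:
        raise PipelineError("normfinder", str(exc)) from exc

    try:
        bk_res = BestKeeper(
            table, dispersion=config.dispersion,
            collapse=config.replicate_mode == "collapse",
            sd_threshold=config.sd_threshold,
        ).fit()
    except Exception as exc:
        raise PipelineError("bestkeeper", str(exc)) from exc
    warnings_.extend(bk_res.warnings_)

    ranks = {"genorm": genorm_res.ranks, "normfinder": nf_res.ranks}
    if config.include_bestkeeper_in_consensus:
        ranks["bestkeeper_cv"] = bk_res.cv_ranks()
    try:
        consensus = mean_rank(pd.DataFrame(ranks))
    except Exception as exc:
        raise PipelineError("consensus", str(exc)) from exc

    v = genorm_res.pairwise_variation_series()
    n, chosen, warned = choose_rg_count(v, cutoff=config.v_cutoff)
    if warned:
        warnings_.append(
            f"no V(n/n+1) below {config.v_cutoff:g}; falling back to n={n}"
        )

    stability = pd.DataFrame(
        {
            "genorm_m": genorm_res.m_final,
            "genorm_rank": genorm_res.ranks,
            "normfinder_value": nf_res.stability,
            "normfinder_rank": nf_res.ranks,
            "mean_rank": consensus.consensus,
            "bestkeeper_cv": bk_res.per_gene["cv"],
            "bestkeeper_sd": bk_res.per_gene["sd"],
        }
    ).sort_values(["mean_rank", "genorm_rank"])
    stability.index.name = "gene"

    for w in warnings_:
        log.warning(w)
    return PipelineReport(
        stability_table=stability,
        v_series=v.values,
        chosen_n=n,
        chosen_genes=chosen or [],
        v_warned=warned,
        config=config,
        config_hash=config.hash(),
        warnings_=warnings_,
    )
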