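"""Quantification-cycle (Cq) data containers and CSV I/O.

The central object is :class:`CqTable`, a genes x samples matrix of Cq
values with per-sample metadata (timepoint, optional group, replicate).
Cq is the PCR cycle at which fluorescence crosses threshold; lower Cq
means more template. Downstream stability analyses consume either the
raw Cq (BestKeeper) or efficiency-transformed relative quantities
(geNorm, NormFinder) produced by :func:`cq_to_quantity`.

Two CSV layouts are supported:

* long  -- columns ``sample_id,timepoint,timepoint_unit,group,replicate,gene,cq``
* wide  -- metadata columns followed by one column per gene

Missing Cq cells (empty or ``NA``) become ``NaN`` and are counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "EfficiencyMap",
    "CqValidationError",
    "read_cq_table",
    "write_cq_table",
    "collapse_replicates",
    "cq_to_quantity",
]

META_COLUMNS = ["timepoint", "timepoint_unit", "group", "replicate"]
LONG_COLUMNS = ["sample_id", *META_COLUMNS, "gene", "cq"]

#: default plausibility band for Cq values (cycles)
CQ_BAND = (5.0, 40.0)


class CqValidationError(ValueError):
    """Raised when a Cq table violates a structural invariant."""


@dataclass
class CqTable:
    """Genes x samples Cq matrix plus sample metadata.

    Parameters
    ----------
    cq : DataFrame
        Index = gene names, columns = sample ids, values = Cq in cycles
        (NaN marks missing).
    meta : DataFrame
        Index = sample ids; columns ``timepoint`` (float), ``timepoint_unit``
        ("hours" or "days"), ``group`` (str or NaN), ``replicate`` (int >= 1).
    """

    cq: pd.DataFrame
    meta: pd.DataFrame
    cq_band: tuple[float, float] = CQ_BAND
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.cq.index.duplicated().any():
            dupes = self.cq.index[self.cq.index.duplicated()].tolist()
            raise CqValidationError(f"duplicate gene names: {dupes}")
        if self.cq.columns.duplicated().any():
            dupes = self.cq.columns[self.cq.columns.duplicated()].tolist()
            raise CqValidationError(f"duplicate sample ids: {dupes}")
        missing_meta = set(self.cq.columns) - set(self.meta.index)
        if missing_meta:
            raise CqValidationError(f"samples without metadata: {sorted(missing_meta)}")
        self.meta = self.meta.loc[list(self.cq.columns)]
        if (self.meta["replicate"] < 1).any():
            raise CqValidationError("replicate indices must be >= 1")
        if (self.meta["timepoint"] < 0).any():
            raise CqValidationError("timepoints must be non-negative")
        lo, hi = self.cq_band
        vals = self.cq.to_numpy()
        finite = np.isfinite(vals)
        if np.isinf(vals).any():
            raise CqValidationError("Cq values must be finite or missing")
        out_of_band = finite & ((vals < lo) | (vals > hi))
        if out_of_band.any():
            self.warnings_.append(
                f"{int(out_of_band.sum())} Cq values outside plausibility band [{lo}, {hi}]"
            )
        if not (self.meta["timepoint"] == 0).any():
            self.warnings_.append("no control (timepoint 0) samples present")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_missing(self) -> int:
        return int(self.cq.isna().to_numpy().sum())

    def control_samples(self) -> list[str]:
        return list(self.meta.index[self.meta["timepoint"] == 0])

    def timepoints(self) -> list[float]:
        return sorted(self.meta["timepoint"].unique())

    def subset_genes(self, genes: list[str]) -> "CqTable":
        unknown = set(genes) - set(self.genes)
        if unknown:
            raise KeyError(f"genes not in table: {sorted(unknown)}")
        return CqTable(self.cq.loc[list(genes)].copy(), self.meta.copy(), self.cq_band)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CqTable):
            return NotImplemented
        return self.cq.equals(other.cq) and self.meta.equals(other.meta)


@dataclass
class EfficiencyMap:
    """Per-gene amplification efficiency as a per-cycle factor.

    A factor of 2.0 means perfect doubling (100% efficiency); the percent
    form e% relates to the factor via ``factor = 1 + e% / 100``. Genes
    absent from the mapping fall back to the default factor 2.0.
    """

    factors: Mapping[str, float] = field(default_factory=dict)
    provenance: Literal["assumed", "fitted"] = "assumed"
    default: float = 2.0

    def __post_init__(self) -> None:
        for gene, f in self.factors.items():
            if not 1.0 < f <= 2.2:
                raise ValueError(
                    f"efficiency factor for {gene} is {f}; must be in (1, 2.2]"
                )

    def factor(self, gene: str) -> float:
        return float(self.factors.get(gene, self.default))

    @classmethod
    def from_percent(
        cls, percents: Mapping[str, float], provenance: str = "assumed"
    ) -> "EfficiencyMap":
        """Build from percent efficiencies (100 -> factor 2.0)."""
        return cls(
            {g: 1.0 + p / 100.0 for g, p in percents.items()}, provenance=provenance
        )


# -- CSV I/O ------------------------------------------------------------------


def _parse_meta(df: pd.DataFrame) -> pd.DataFrame:
    meta = df[["sample_id", *META_COLUMNS]].drop_duplicates("sample_id")
    meta = meta.set_index("sample_id")
    meta["timepoint"] = meta["timepoint"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    meta["group"] = meta["group"].where(meta["group"].notna(), None)
    return meta


def read_cq_table(path: str | Path, layout: Literal["long", "wide"] = "long") -> CqTable:
    """Read a Cq CSV in long or wide layout into a validated :class:`CqTable`.

    Unparseable Cq cells become missing markers (NaN) and are counted in
    ``table.warnings_``. A duplicated (gene, sample) pair is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str}, na_values=["NA"])
    if layout == "long":
        required = set(LONG_COLUMNS)
        missing = required - set(df.columns)
        if missing:
            raise CqValidationError(f"long CSV missing columns: {sorted(missing)}")
        dup = df.duplicated(subset=["gene", "sample_id"], keep=False)
        if dup.any():
            first = df.loc[dup].iloc[0]
            raise CqValidationError(
                f"duplicate Cq entry for gene {first['gene']}, sample {first['sample_id']}"
            )
        cq_raw = df["cq"]
        cq_num = pd.to_numeric(cq_raw, errors="coerce")
        n_unparseable = int((cq_num.isna() & cq_raw.notna()).sum())
        df = df.assign(cq=cq_num)
        wide = df.pivot(index="gene", columns="sample_id", values="cq")
        # preserve first-appearance order of genes and samples
        wide = wide.loc[df["gene"].drop_duplicates(), df["sample_id"].drop_duplicates()]
        wide.index.name = None
        wide.columns.name = None
        meta = _parse_meta(df)
        table = CqTable(wide, meta)
    elif layout == "wide":
        gene_cols = [c for c in df.columns if c not in ("sample_id", *META_COLUMNS)]
        if df["sample_id"].duplicated().any():
            s = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CqValidationError(f"duplicate sample id {s} in wide CSV")
        n_unparseable = 0
        for c in gene_cols:
            num = pd.to_numeric(df[c], errors="coerce")
            n_unparseable += int((num.isna() & df[c].notna()).sum())
            df[c] = num
        wide = df.set_index("sample_id")[gene_cols].T.astype(float)
        wide.index.name = None
        wide.columns.name = None
        table = CqTable(wide, _parse_meta(df))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if n_unparseable:
        table.warnings_.append(f"{n_unparseable} unparseable Cq cells set to missing")
    return table


def write_cq_table(
    table: CqTable, path: str | Path, layout: Literal["long", "wide"] = "long"
) -> None:
    """Write a CqTable to CSV, inverse of :func:`read_cq_table`."""
    path = Path(path)
    meta = table.meta.reset_index(names="sample_id")
    if layout == "long":
        long = table.cq.stack(future_stack=True).rename("cq").reset_index()
        long.columns = ["gene", "sample_id", "cq"]
        out = long.merge(meta, on="sample_id")[LONG_COLUMNS]
        # stable order: gene-major, samples in table order
        out["__s"] = out["sample_id"].map({s: i for i, s in enumerate(table.samples)})
        out["__g"] = out["gene"].map({g: i for i, g in enumerate(table.genes)})
        out = out.sort_values(["__g", "__s"]).drop(columns=["__s", "__g"])
        out.to_csv(path, index=False)
    elif layout == "wide":
        wide = table.cq.T.reset_index(names="sample_id")
        out = meta.merge(wide, on="sample_id")
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# -- transformations ----------------------------------------------------------


def collapse_replicates(
    table: CqTable, mode: Literal["mean", "median"] = "mean"
) -> CqTable:
    """Collapse biological replicates to one sample per (timepoint, group).

    Cq is averaged (or median-ed) over replicates, skipping missing values.
    A (gene, timepoint) cell whose replicates are all missing stays missing
    and is reported in ``warnings_``.
    """
    if mode not in ("mean", "median"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    meta = table.meta
    key = list(zip(meta["timepoint"], meta["timepoint_unit"], meta["group"]))
    groups: dict[tuple, list[str]] = {}
    for sample, k in zip(meta.index, key):
        groups.setdefault(k, []).append(sample)

    cols, rows_meta = {}, []
    all_missing = 0
    for (tp, unit, grp), samples in groups.items():
        block = table.cq[samples]
        agg = block.mean(axis=1) if mode == "mean" else block.median(axis=1)
        all_missing += int((block.isna().all(axis=1)).sum())
        unit_tag = {"hours": "h", "days": "d"}.get(unit, unit)
        label = f"t{tp:g}{unit_tag}" + (f"_{grp}" if grp is not None else "")
        cols[label] = agg
        rows_meta.append(
            {"sample_id": label, "timepoint": tp, "timepoint_unit": unit,
             "group": grp, "replicate": 1}
        )
    cq = pd.DataFrame(cols)
    new_meta = pd.DataFrame(rows_meta).set_index("sample_id")
    out = CqTable(cq, new_meta, table.cq_band)
    if all_missing:
        out.warnings_.append(
            f"{all_missing} (gene, timepoint) cells had all replicates missing"
        )
    return out


def cq_to_quantity(
    table: CqTable,
    eff: EfficiencyMap | None = None,
    anchor: Literal["min", "mean"] = "min",
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Transform Cq into relative quantities Q = factor ** (anchor_Cq - Cq).

    With the default ``min`` anchor every gene's best (lowest-Cq) sample has
    quantity exactly 1 and all quantities lie in (0, 1]; the ``mean`` anchor
    differs only by a per-gene scale factor, which no stability measure
    sees. Samples with any missing gene are dropped (geNorm and NormFinder
    require complete cases) and the count recorded via a warning.
    """
    eff = eff or EfficiencyMap()
    cq = table.cq
    if drop_incomplete:
        complete = cq.notna().all(axis=0)
        n_drop = int((~complete).sum())
        if n_drop:
            warnings.warn(
                f"dropping {n_drop} samples with missing Cq for quantity transform",
                stacklevel=2,
            )
        cq = cq.loc[:, complete]
    factors = np.array([eff.factor(g) for g in cq.index])[:, None]
    ref = cq.min(axis=1) if anchor == "min" else cq.mean(axis=1)
    q = np.power(factors, ref.to_numpy()[:, None] - cq.to_numpy())
    return pd.DataFrame(q, index=cq.index, columns=cq.columns)
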