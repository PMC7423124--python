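"""Cross-method rank aggregation for reference-gene stability.

Each stability method yields a rank order (possibly fractional — geNorm's
tied best pair sits at 1.5). The consensus is the per-gene arithmetic mean
of the method ranks, re-ranked competition-style: tied genes share the
minimum rank of their tie block and the next distinct mean skips by the
block size (1, 2, 3, 3, 5, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["ConsensusRanking", "mean_rank", "geometric_mean_rank"]


@dataclass
class ConsensusRanking:
    """Mean of method ranks and the resulting competition-style consensus."""

    method_ranks: pd.DataFrame   # genes x methods
    mean: pd.Series              # per-gene mean of method ranks
    consensus: pd.Series         # integer competition ranks

    def summary(self) -> pd.DataFrame:
        out = self.method_ranks.copy()
        out["mean_rank"] = self.mean
        out["consensus"] = self.consensus
        return out.sort_values(["consensus", "mean_rank"])


def _as_frame(
    ranks_by_method: Mapping[str, Mapping[str, float]] | pd.DataFrame
) -> pd.DataFrame:
    if isinstance(ranks_by_method, pd.DataFrame):
        return ranks_by_method.astype(float)
    frames = {m: pd.Series(dict(r), dtype=float) for m, r in ranks_by_method.items()}
    genes_per_method = [set(s.index) for s in frames.values()]
    union = set().union(*genes_per_method)
    for m, s in frames.items():
        diff = union.symmetric_difference(set(s.index))
        if diff:
            raise ValueError(
                f"inconsistent gene sets across methods; symmetric difference "
                f"involving {m}: {sorted(diff)}"
            )
    return pd.DataFrame(frames)


def mean_rank(
    ranks_by_method: Mapping[str, Mapping[str, float]] | pd.DataFrame
) -> ConsensusRanking:
    """Aggregate per-method ranks into a competition-ranked consensus.

    Every method must rank the same gene set; a mismatch raises with the
    symmetric difference listed. Lower consensus rank = more stable.
    """
    frame = _as_frame(ranks_by_method)
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"genes missing a rank in some method: {bad}")
    if frame.shape[1] < 1:
        raise ValueError("need at least one method")
    means = frame.mean(axis=1)
    consensus = means.rank(method="min").astype(int)
    return ConsensusRanking(
        method_ranks=frame, mean=means.rename("mean_rank"),
        consensus=consensus.rename("consensus"),
    )


def geometric_mean_rank(
    ranks_by_method: Mapping[str, Mapping[str, float]] | pd.DataFrame
) -> pd.Series:
    """Geometric-mean rank aggregation (comprehensive-ranking style).

    Provided as a clearly labelled extra; the reproduction pathway uses
    :func:`mean_rank` on exactly the geNorm and NormFinder orders.
    """
    frame = _as_frame(ranks_by_method)
    gm = frame.prod(axis=1) ** (1.0 / frame.shape[1])
    return gm.rename("geomean_rank")
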