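"""geNorm reference-gene stability.

The geNorm expression-stability measure M of a gene is the arithmetic mean
of the pairwise variations V_jk between that gene and every other candidate,
where V_jk is the sample standard deviation (n-1 denominator) of the
log2 expression ratio A_jk(s) = log2(Q_j(s) / Q_k(s)) across samples. Two
ideal reference genes have a constant expression ratio in every sample, so
V = 0; regulation or noise in either gene inflates V. Genes are ranked by
iterative exclusion: the highest-M gene is removed and M recomputed until
two genes remain, which are tied at rank 1.5 (their mutual ratio cannot
distinguish them).

The pairwise-variation series V(n/n+1) compares normalization factors
(geometric means of the n and n+1 most stable genes) and drives the
"how many reference genes are enough" decision with the conventional
0.15 cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeNorm", "GeNormResults", "PairwiseVariationSeries",
           "pairwise_variation_matrix", "m_values", "choose_rg_count"]


def _check_quantities(q: pd.DataFrame) -> pd.DataFrame:
    q = q.astype(float)
    if q.isna().any().any():
        raise ValueError("quantity matrix must be complete (no missing values)")
    if (q.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    if q.shape[1] < 2:
        raise ValueError("need at least 2 samples (pairwise SD undefined)")
    if q.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    return q


def pairwise_variation_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix V_jk of pairwise log2-ratio standard deviations.

    V_jk = sd_{n-1}( log2(Q_j(s) / Q_k(s)) ) over samples s; V_jj = 0.
    """
    q = _check_quantities(q)
    logq = np.log2(q.to_numpy())
    k = logq.shape[0]
    v = np.zeros((k, k))
    for j in range(k):
        diff = logq[j] - logq          # A_jk over all k at once
        v[j] = diff.std(axis=1, ddof=1)
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=q.index, columns=q.index)


def m_values(q: pd.DataFrame) -> pd.Series:
    """Stability measure M_j = mean over k != j of V_jk (lower = more stable)."""
    v = pairwise_variation_matrix(q)
    k = v.shape[0]
    if k == 2:
        off = v.iloc[0, 1]
        return pd.Series([off, off], index=v.index, name="M")
    m = (v.sum(axis=1)) / (k - 1)
    m.name = "M"
    return m


@dataclass
class PairwiseVariationSeries:
    """V(n/n+1) values for n = 2..K-1 along a stability ranking."""

    values: pd.Series            # index n, value V(n/n+1)
    gene_order: list[str]        # most stable first

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GeNormResults:
    """Ranking and stability values from geNorm iterative exclusion.

    Attributes
    ----------
    m_final : Series
        Per-gene M at the step the gene was excluded; the best pair share
        their mutual V value.
    ranks : Series
        Exclusion-order ranks {1.5, 1.5, 3, 4, ..., K} (1.5 = tied best pair).
    m_trajectory : list of Series
        M values of the surviving gene set at each exclusion step.
    pairwise_variation : DataFrame
        V_jk on the full gene set (step 0).
    """

    m_final: pd.Series
    ranks: pd.Series
    m_trajectory: list[pd.Series]
    pairwise_variation: pd.DataFrame
    _quantities: pd.DataFrame = field(repr=False)

    @property
    def gene_order(self) -> list[str]:
        """Genes from most to least stable (tied pair first, in name order)."""
        return sorted(self.ranks.index, key=lambda g: (self.ranks[g], g))

    def pairwise_variation_series(self) -> PairwiseVariationSeries:
        """V(n/n+1) for n = 2..K-1 along this ranking.

        NF_n(s) is the geometric mean of the n most stable genes' quantities
        in sample s; V(n/n+1) is the sample SD over s of log2(NF_n/NF_{n+1}).
        """
        order = self.gene_order
        k = len(order)
        logq = np.log2(self._quantities.loc[order].to_numpy())
        vals = {}
        for n in range(2, k):
            log_nf_n = logq[:n].mean(axis=0)          # log2 geometric mean
            log_nf_n1 = logq[: n + 1].mean(axis=0)
            vals[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
        series = pd.Series(vals, name="V")
        series.index.name = "n"
        return PairwiseVariationSeries(series, order)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"M": self.m_final, "rank": self.ranks}).sort_values(
            "rank", kind="stable"
        )


class GeNorm:
    """geNorm stability model over a relative-quantity matrix.

    Parameters
    ----------
    quantities : DataFrame
        Genes x samples positive relative quantities (see
        :func:`refstab.cq_data.cq_to_quantity`).
    """

    def __init__(self, quantities: pd.DataFrame):
        self.quantities = _check_quantities(quantities)

    def fit(self) -> GeNormResults:
        """Rank genes by iterative exclusion of the highest-M gene.

        Ties on the argmax M are broken deterministically by removing the
        lexicographically last gene name. The final two genes share rank
        1.5 and their mutual pairwise variation as M.
        """
        q = self.quantities
        if q.shape[0] < 3:
            raise ValueError("iterative exclusion needs >= 3 genes")
        v0 = pairwise_variation_matrix(q)
        current = q.copy()
        m_final: dict[str, float] = {}
        ranks: dict[str, float] = {}
        trajectory: list[pd.Series] = []
        while current.shape[0] > 2:
            m = m_values(current)
            trajectory.append(m)
            worst_m = m.max()
            # lexicographically last among the argmax ties
            worst = sorted(m.index[m == worst_m])[-1]
            m_final[worst] = float(m[worst])
            ranks[worst] = float(current.shape[0])
            current = current.drop(index=worst)
        m2 = m_values(current)
        trajectory.append(m2)
        for g in current.index:
            m_final[g] = float(m2[g])
            ranks[g] = 1.5
        genes = list(q.index)
        return GeNormResults(
            m_final=pd.Series({g: m_final[g] for g in genes}, name="M"),
            ranks=pd.Series({g: ranks[g] for g in genes}, name="rank"),
            m_trajectory=trajectory,
            pairwise_variation=v0,
            _quantities=q,
        )


def choose_rg_count(
    series: "PairwiseVariationSeries | pd.Series",
    cutoff: float = 0.15,
    gene_order: list[str] | None = None,
) -> tuple[int, list[str] | None, bool]:
    """Smallest n with V(n/n+1) below the cut-off, and the genes to use.

    Accepts a :class:`PairwiseVariationSeries` or a bare Series indexed by
    n (then ``gene_order``, if given, supplies the gene list). Returns
    ``(n, genes, warned)``. If no V value falls below the cut-off the full
    candidate set is returned with ``warned=True``; an empty series (fewer
    than 3 genes) returns n=2 with a warning.
    """
    if isinstance(series, PairwiseVariationSeries):
        values, gene_order = series.values, series.gene_order
    else:
        values = series
    k = len(gene_order) if gene_order is not None else (
        int(values.index.max()) + 1 if len(values) else 2
    )

    def pick(n: int) -> list[str] | None:
        return gene_order[:n] if gene_order is not None else None

    if len(values) == 0:
        return 2, pick(2), True
    below = values[values < cutoff]
    if len(below) == 0:
        return k, pick(k), True
    n = int(below.index[0])
    return n, pick(n), False
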