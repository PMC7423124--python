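"""NormFinder model-based reference-gene stability.

NormFinder treats log-scale expression as an additive two-way layout,

    y_ij = alpha_i + beta_j + eps_ij,      eps_ij ~ N(0, sigma_i^2),

with gene effects alpha_i, sample effects beta_j and a gene-specific error
variance sigma_i^2 that quantifies how much gene i fluctuates once overall
expression level and per-sample loading are removed. The stability value
is sigma_hat_i (log2 units); lower is more stable.

Because the sample effect is estimated from the candidate genes themselves,
the naive per-gene residual variance is biased: each gene contributes to the
sample mean it is compared against. With l genes and n samples,

    E[ sum_j r_ij^2 / (n-1) ] = (1 - 2/l) sigma_i^2 + S / l^2,

where r_ij are the double-centred residuals and S = sum_i sigma_i^2. The
moment estimator inverts this relation (summing over genes gives
S_hat = l/(l-1) * sum_i m_i) and clamps negative solutions at zero.

The grouped mode additionally estimates, per gene and sample group, an
intergroup difference d_ig (how far the gene's group average deviates from
the candidate-set consensus) and combines a shrunken |d| with the sampling
noise of d into one stability value that grows with both systematic
between-group regulation and within-group scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormFinder", "NormFinderResults"]


def _log_residual_moments(y: np.ndarray) -> np.ndarray:
    """Per-gene mean squared double-centred residual, n-1 denominator."""
    n = y.shape[1]
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    return (r**2).sum(axis=1) / (n - 1)


def _variance_estimates(y: np.ndarray) -> tuple[np.ndarray, int]:
    """Bias-corrected per-gene variances for the two-way layout.

    Returns (sigma2_hat, n_clamped). Requires l >= 3 genes.
    """
    l = y.shape[0]
    if l < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    m = _log_residual_moments(y)
    s_hat = m.sum() * l / (l - 1)
    sigma2 = (m - s_hat / l**2) * l / (l - 2)
    n_clamped = int((sigma2 < 0).sum())
    return np.clip(sigma2, 0.0, None), n_clamped


@dataclass
class NormFinderResults:
    """Per-gene stability values, variances and ranks."""

    stability: pd.Series          # sigma_hat_i, log2 units; lower = more stable
    variance: pd.Series           # sigma2_hat_i
    ranks: pd.Series              # 1..K, ordinal on stability (ties by name)
    n_clamped: int                # negative variance estimates clamped to 0
    grouped: bool = False
    intergroup_difference: pd.DataFrame | None = None   # genes x groups, d_ig
    intragroup_variance: pd.DataFrame | None = None     # genes x groups

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stability": self.stability, "variance": self.variance, "rank": self.ranks}
        ).sort_values("rank")


class NormFinder:
    """NormFinder stability model over a relative-quantity matrix.

    Parameters
    ----------
    quantities : DataFrame
        Genes x samples positive quantities; log2 is taken internally.
    groups : Series or mapping, optional
        Sample -> group label. When given, stability combines intergroup
        differences with intragroup variances; each group needs >= 2
        samples.
    """

    def __init__(self, quantities: pd.DataFrame, groups: pd.Series | dict | None = None):
        q = quantities.astype(float)
        if q.isna().any().any():
            raise ValueError("quantity matrix must be complete")
        if (q.to_numpy() <= 0).any():
            raise ValueError("quantities must be strictly positive")
        self.quantities = q
        self.log_q = np.log2(q.to_numpy())
        if groups is not None:
            groups = pd.Series(dict(groups) if isinstance(groups, dict) else groups)
            missing = set(q.columns) - set(groups.index)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")
            groups = groups.loc[list(q.columns)]
            counts = groups.value_counts()
            singletons = counts.index[counts < 2].tolist()
            if singletons:
                raise ValueError(f"groups with a single sample: {singletons}")
        self.groups = groups

    def fit(self) -> NormFinderResults:
        if self.groups is None:
            return self._fit_ungrouped()
        return self._fit_grouped()

    def _fit_ungrouped(self) -> NormFinderResults:
        genes = list(self.quantities.index)
        sigma2, n_clamped = _variance_estimates(self.log_q)
        stability = pd.Series(np.sqrt(sigma2), index=genes, name="stability")
        return NormFinderResults(
            stability=stability,
            variance=pd.Series(sigma2, index=genes, name="variance"),
            ranks=_rank(stability),
            n_clamped=n_clamped,
        )

    def _fit_grouped(self) -> NormFinderResults:
        genes = list(self.quantities.index)
        l = len(genes)
        if l < 3:
            raise ValueError("NormFinder needs >= 3 genes")
        group_labels = list(dict.fromkeys(self.groups))
        n_groups = len(group_labels)
        y = self.log_q

        sigma2 = np.empty((l, n_groups))
        d = np.empty((l, n_groups))
        n_g = np.empty(n_groups)
        n_clamped = 0
        grand_gene_mean = y.mean(axis=1)           # over all samples
        grand_mean = y.mean()
        for gi, g in enumerate(group_labels):
            cols = np.asarray(self.groups == g)
            yg = y[:, cols]
            n_g[gi] = yg.shape[1]
            s2, nc = _variance_estimates(yg)
            sigma2[:, gi] = s2
            n_clamped += nc
            # gene-by-group interaction: deviation of the gene's group mean
            # from what gene level + group level alone predict
            d[:, gi] = (
                yg.mean(axis=1) - grand_gene_mean - yg.mean() + grand_mean
            )

        # shrink d toward 0 by the ratio of between-group signal to its
        # sampling noise (James-Stein-style; vanishes when d is pure noise)
        samp_var = sigma2 / n_g[None, :]
        gamma2 = max(
            0.0,
            (d**2).sum() / (l * max(n_groups - 1, 1)) - samp_var.mean(),
        )
        shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else np.zeros_like(samp_var)
        d_shrunk = d * shrink
        # per-(gene, group) contribution: |shrunken d| + posterior SD of d
        post_var = np.where(gamma2 > 0, shrink * samp_var, samp_var)
        rho = np.abs(d_shrunk) + np.sqrt(post_var)
        stability = pd.Series(rho.mean(axis=1), index=genes, name="stability")
        return NormFinderResults(
            stability=stability,
            variance=pd.Series(sigma2.mean(axis=1), index=genes, name="variance"),
            ranks=_rank(stability),
            n_clamped=n_clamped,
            grouped=True,
            intergroup_difference=pd.DataFrame(d, index=genes, columns=group_labels),
            intragroup_variance=pd.DataFrame(sigma2, index=genes, columns=group_labels),
        )


def _rank(stability: pd.Series) -> pd.Series:
    order = sorted(stability.index, key=lambda g: (stability[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").loc[
        stability.index
    ]
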