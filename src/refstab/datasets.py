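"""Published reference-gene stability results bundled for reproduction.

These are the printed per-gene stability tables of a cold-stress RT-qPCR
study in the mushroom-forming fungus *Cordyceps militaris*: 12 candidate
reference genes evaluated by geNorm, NormFinder and BestKeeper over short
(hours) and long (days) cold treatments, plus the primer amplification
efficiencies and the pairwise-variation values the study reported. The raw
Cq measurements were not deposited, so these derived tables are the inputs
for reproducing the study's consensus ranking and reference-gene-count
decisions.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "short_period_stability",
    "long_period_stability",
    "amplification_efficiency_percent",
    "pairwise_variation_values",
]

_COLUMNS = [
    "genorm_m", "genorm_rank", "normfinder_value", "normfinder_rank",
    "mean_rank", "bestkeeper_cv", "bestkeeper_sd",
]

_SHORT = {
    "UBC":   (0.336, 1.5, 0.141, 1, 1, 4.501, 0.882),
    "PP2A":  (0.336, 1.5, 0.248, 3, 2, 3.596, 0.872),
    "GTPB":  (0.383, 3, 0.287, 4, 3, 4.647, 1.203),
    "CYP":   (0.451, 4, 0.303, 5, 5, 2.858, 0.744),
    "UBQ":   (0.500, 5, 0.244, 2, 3, 4.725, 1.222),
    "RPS":   (0.555, 6, 0.409, 7, 6, 3.969, 0.710),
    "FBOX":  (0.575, 7, 0.381, 6, 6, 3.115, 0.819),
    "EF1A":  (0.612, 8, 0.419, 8, 8, 6.658, 1.431),
    "TUB":   (0.657, 9, 0.561, 11, 9, 3.317, 0.751),
    "GAPDH": (0.708, 10, 0.541, 10, 9, 7.141, 1.557),
    "ACT":   (0.751, 11, 0.490, 9, 9, 3.924, 1.016),
    "PGK":   (0.908, 12, 1.116, 12, 12, 6.299, 1.600),
}

_LONG = {
    "TUB":   (0.254, 1.5, 0.308, 4, 2, 4.934, 0.711),
    "EF1A":  (0.254, 1.5, 0.360, 6, 5, 6.359, 1.930),
    "UBQ":   (0.470, 3, 0.202, 2, 1, 4.066, 0.701),
    "GAPDH": (0.523, 4, 0.247, 3, 4, 4.589, 0.949),
    "CYP":   (0.548, 5, 0.123, 1, 3, 3.560, 0.693),
    "PP2A":  (0.571, 6, 0.404, 7, 7, 5.381, 1.442),
    "GTPB":  (0.599, 7, 0.319, 5, 6, 5.670, 1.426),
    "RPS":   (0.655, 8, 0.489, 8, 8, 3.882, 0.704),
    "FBOX":  (0.701, 9, 0.543, 9, 9, 2.487, 0.644),
    "ACT":   (0.764, 10, 0.641, 10, 10, 2.935, 0.743),
    "UBC":   (0.830, 11, 0.730, 11, 11, 8.127, 1.792),
    "PGK":   (1.121, 12, 1.733, 12, 12, 7.325, 1.786),
}

#: primer amplification efficiencies (%) per candidate gene
_EFFICIENCY_PERCENT = {
    "ACT": 99.6, "TUB": 97.5, "UBC": 101.3, "EF1A": 106.2, "GAPDH": 102.3,
    "PP2A": 105.7, "UBQ": 102.5, "PGK": 98.9, "RPS": 97.8, "FBOX": 101.3,
    "CYP": 95.5, "GTPB": 103.4,
}

#: reported pairwise-variation values V(n/n+1) per period
_V_VALUES = {
    "short": {2: 0.124},
    "long": {2: 0.188, 3: 0.125},
}


def _frame(data: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(data, orient="index", columns=_COLUMNS)


def short_period_stability() -> pd.DataFrame:
    """Per-gene stability table for the short (hours) cold series."""
    return _frame(_SHORT)


def long_period_stability() -> pd.DataFrame:
    """Per-gene stability table for the long (days) cold series."""
    return _frame(_LONG)


def amplification_efficiency_percent() -> pd.Series:
    """Reported primer efficiencies in percent (100 = perfect doubling)."""
    return pd.Series(_EFFICIENCY_PERCENT, name="efficiency_percent")


def pairwise_variation_values(period: str) -> pd.Series:
    """Reported V(n/n+1) values (index n) for ``period`` in {short, long}."""
    try:
        vals = _V_VALUES[period]
    except KeyError:
        raise ValueError(f"period must be 'short' or 'long', got {period!r}") from None
    s = pd.Series(vals, name="V")
    s.index.name = "n"
    return s
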