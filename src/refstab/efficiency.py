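"""Amplification-efficiency estimation from serial-dilution standard curves.

A 10-fold dilution series of template gives Cq values that are linear in
log10(template amount); the slope determines the per-cycle amplification
efficiency via E% = (10^(-1/slope) - 1) * 100. A perfectly doubling assay
has slope -1/log10(2) = -3.3219 and efficiency 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "check_efficiency_range"]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(template amount) and derived efficiencies."""

    slope: float                 # cycles per log10 dilution step
    intercept: float             # cycles at amount 1
    r_squared: float
    efficiency_percent: float    # (10^(-1/slope) - 1) * 100
    efficiency_factor: float     # 1 + efficiency_percent / 100
    n_points: int

    def summary(self) -> str:
        return (
            f"slope={self.slope:.4f} intercept={self.intercept:.2f} "
            f"R2={self.r_squared:.4f} efficiency={self.efficiency_percent:.1f}% "
            f"(factor {self.efficiency_factor:.3f})"
        )


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Fit a qPCR standard curve from (relative template amount, Cq) pairs.

    Ordinary least squares of Cq on log10(amount) — the universal
    standard-curve convention. Requires at least 3 distinct dilution
    levels; a non-negative slope (no amplification gain with template)
    is rejected as a non-amplifying series.
    """
    pts = [(float(a), float(c)) for a, c in points]
    if any(a <= 0 for a, _ in pts):
        raise ValueError("template amounts must be positive")
    levels = {a for a, _ in pts}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct dilution levels, got {len(levels)}"
        )
    x = np.log10([a for a, _ in pts])
    y = np.array([c for _, c in pts])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("non-amplifying series: standard-curve slope is >= 0")
    eff_pct = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_percent=float(eff_pct),
        efficiency_factor=float(1.0 + eff_pct / 100.0),
        n_points=len(pts),
    )


def check_efficiency_range(
    curve: StandardCurve,
    lo: float = 90.0,
    hi: float = 110.0,
    r2_warn: float = 0.98,
) -> tuple[bool, str]:
    """Verdict on whether a curve's efficiency falls in the acceptable band.

    Defaults to the conventional 90–110% acceptance band, with a soft
    warning when r² drops below 0.98.
    """
    e = curve.efficiency_percent
    ok = lo <= e <= hi
    msg = f"efficiency {e:.1f}% {'within' if ok else 'outside'} [{lo:g}%, {hi:g}%]"
    if curve.r_squared < r2_warn:
        msg += f"; warning: r²={curve.r_squared:.3f} < {r2_warn}"
    return ok, msg


def slope_for_factor(factor: float) -> float:
    """Standard-curve slope implied by an amplification factor (round-trip)."""
    if factor <= 1:
        raise ValueError("amplification factor must exceed 1")
    return -1.0 / np.log10(factor)


def fit_dilution_table(rows: Sequence[tuple[str, float, float]]) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from (gene, dilution, cq) rows."""
    by_gene: dict[str, list[tuple[float, float]]] = {}
    for gene, amount, cq in rows:
        by_gene.setdefault(gene, []).append((amount, cq))
    return {g: fit_standard_curve(pts) for g, pts in by_gene.items()}
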