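"""Single-chemical contribution curves and comparison against a confidence band.

A chemical present at fraction p of a fixed-ratio mixture receives dose
p * X when the total mixture concentration is X.  Its "calculated
contribution" to the mixture effect is therefore its own fitted curve
re-expressed on the mixture-concentration axis — a rigid shift to the right
by the factor 1/p in log concentration:

    contribution(X) = E_single(p * X)

Contribution curves and model prediction curves are judged against the 95 %
confidence band of the experimental mixture fit: a curve left of the band
reaches a given effect at lower total concentration than the data support
(the signature of antagonism when it is a model prediction).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .doseresponse import ConfidenceBand, HillFit, hill_effect
from .errors import InputError
from .mixture import PredictionCurve

# a verdict side must account for this share of outside-band points
_DOMINANCE = 0.9
_INSIDE_FRACTION = 0.95


@dataclasses.dataclass(frozen=True)
class ContributionCurve:
    """A chemical's fitted curve on the total-mixture-concentration axis."""

    chemical_id: str
    concentrations: np.ndarray  # total mixture µM
    effects: np.ndarray  # % of control
    fraction: float

    def __post_init__(self):
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))


@dataclasses.dataclass(frozen=True)
class BandComparison:
    """Location of a curve relative to a confidence band.

    ``verdict`` is "inside" when >= 95 % of evaluable grid points fall within
    the band; otherwise "left_of_band" / "right_of_band" when one side
    dominates the outside points, else "mixed".
    """

    curve_id: str
    n_points: int
    fraction_inside: float
    fraction_left: float
    fraction_right: float
    verdict: str


def contribution_curve(
    fit: HillFit,
    fraction: float,
    grid: Sequence[float],
) -> ContributionCurve:
    """Re-express a significant single-chemical fit on the mixture axis."""
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must lie in (0, 1], got {fraction}")
    if not fit.significant or fit.direction == "none":
        raise InputError(f"{fit.chemical_id}: contribution requires a significant fit")
    grid = np.asarray(grid, dtype=float)
    return ContributionCurve(
        chemical_id=fit.chemical_id,
        concentrations=grid,
        effects=np.asarray(hill_effect(fit, fraction * grid), dtype=float),
        fraction=fraction,
    )


def _monotone_direction(y: np.ndarray) -> int:
    """+1 increasing, -1 decreasing, 0 neither (within tiny tolerance)."""
    dy = np.diff(y)
    if np.all(dy >= -1e-9):
        return 1
    if np.all(dy <= 1e-9):
        return -1
    return 0


def _invert_edge(conc: np.ndarray, edge: np.ndarray, effect: float, sense: int) -> float | None:
    """Concentration at which a monotone band edge crosses ``effect``."""
    lo, hi = min(edge[0], edge[-1]), max(edge[0], edge[-1])
    if not lo <= effect <= hi:
        return None
    if sense < 0:  # decreasing: reverse for np.interp
        return float(np.interp(effect, edge[::-1], conc[::-1]))
    return float(np.interp(effect, edge, conc))


def compare_to_band(
    curve: ContributionCurve | PredictionCurve,
    band: ConfidenceBand,
) -> BandComparison:
    """Classify each curve point as inside / left of / right of the band.

    Side is measured horizontally (in log concentration, at matched effect
    level) where the band edges are monotone and invertible at that effect;
    otherwise vertically at the matched concentration.  "Left" means the
    curve reaches a given effect at lower total concentration than the band.
    """
    bc = band.concentrations
    cc = curve.concentrations
    in_range = (cc >= bc.min()) & (cc <= bc.max())
    if int(in_range.sum()) < 10:
        raise InputError("curve and band grids overlap on fewer than 10 points")
    sense = _monotone_direction((band.lower + band.upper) / 2)

    n_inside = n_left = n_right = 0
    atol = 1e-9
    for c, e in zip(cc[in_range], curve.effects[in_range]):
        lo = float(np.interp(c, bc, band.lower))
        hi = float(np.interp(c, bc, band.upper))
        if lo - atol <= e <= hi + atol:
            n_inside += 1
            continue
        side = None
        if sense != 0:
            # band occupies [c_enter, c_exit] at effect level e
            if sense < 0:  # inhibitory: upper edge reaches e later than lower
                c_enter = _invert_edge(bc, band.upper, e, sense)
                c_exit = _invert_edge(bc, band.lower, e, sense)
            else:
                c_enter = _invert_edge(bc, band.lower, e, sense)
                c_exit = _invert_edge(bc, band.upper, e, sense)
            if c_enter is not None and c < c_enter:
                side = "left"
            elif c_exit is not None and c > c_exit:
                side = "right"
        if side is None:
            # vertical fallback: stronger-than-band effect at matched
            # concentration means the curve is shifted left
            stronger = e < lo if sense <= 0 else e > hi
            side = "left" if stronger else "right"
        if side == "left":
            n_left += 1
        else:
            n_right += 1

    n = n_inside + n_left + n_right
    f_in, f_l, f_r = n_inside / n, n_left / n, n_right / n
    if f_in >= _INSIDE_FRACTION:
        verdict = "inside"
    else:
        outside = n_left + n_right
        if n_left >= _DOMINANCE * outside:
            verdict = "left_of_band"
        elif n_right >= _DOMINANCE * outside:
            verdict = "right_of_band"
        else:
            verdict = "mixed"
    curve_id = getattr(curve, "chemical_id", None) or getattr(curve, "model", "curve")
    return BandComparison(
        curve_id=curve_id,
        n_points=n,
        fraction_inside=f_in,
        fraction_left=f_l,
        fraction_right=f_r,
        verdict=verdict,
    )
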