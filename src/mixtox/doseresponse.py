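"""Significance gating, constrained Hill fitting and confidence bands.

Single-chemical (and experimental-mixture) concentration-response data from
steroidogenesis assays such as H295R are expressed in % of the untreated
control (100 = no effect).  The fitting protocol is deliberately rigid:

* a dataset is only fitted if a Kruskal-Wallis test across concentration
  groups (control included) is significant;
* the model is a three-parameter logistic with the Hill slope fixed at 1 and
  the bottom (control) level fixed at 100 %, so only the EC50 — and for
  stimulatory data the plateau — is estimated;
* for inhibitory responses the plateau ("top") is pinned to the lowest
  per-concentration mean response; for stimulatory responses it is estimated
  but bounded above by the highest per-concentration mean.

With the slope fixed at 1 the fitted curve is

    E(c) = 100 + (top - 100) * c / (EC50 + c)

which is exactly invertible, a property the concentration-addition mixture
model relies on.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DirectionAmbiguityError,
    EffectRangeError,
    FitConvergenceError,
    InputError,
    NotSignificantError,
)

CONTROL_LEVEL = 100.0

Direction = Literal["inhibitory", "stimulatory", "none"]

# log10(EC50 / µM) search window for the constrained fits; generous relative
# to the 0.04-30 µM tested range so boundary estimates signal poor data.
_LOG_EC50_BOUNDS = (-8.0, 8.0)
_N_MULTISTART = 5


@dataclasses.dataclass(frozen=True)
class ResponseDataset:
    """Replicated concentration-response measurements for one chemical/endpoint.

    Concentration 0 rows are the untreated controls that define the 100 %
    level; responses are assumed pre-normalised to % of control.
    """

    chemical_id: str
    endpoint: str
    concentrations: np.ndarray  # µM, 0 = control
    responses: np.ndarray  # % of control, > 0
    replicates: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise InputError("concentrations and responses must be 1-D arrays of equal length")
        if conc.size == 0:
            raise InputError(f"{self.chemical_id}: empty dataset")
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise InputError(f"{self.chemical_id}: concentrations must be finite and >= 0")
        if np.any(resp <= 0) or not np.all(np.isfinite(resp)):
            raise InputError(f"{self.chemical_id}: responses must be finite and > 0 (% of control)")
        rep = self.replicates
        if rep is None:
            rep = _default_replicates(conc)
        rep = np.asarray(rep, dtype=int)
        if rep.shape != conc.shape:
            raise InputError("replicate index must match data length")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "replicates", rep)

    @property
    def levels(self) -> np.ndarray:
        """Sorted unique non-zero concentrations (µM)."""
        c = np.unique(self.concentrations)
        return c[c > 0]

    def group_means(self, include_control: bool = False) -> pd.Series:
        """Mean response per concentration, indexed by concentration."""
        s = pd.Series(self.responses).groupby(self.concentrations).mean()
        if not include_control:
            s = s[s.index > 0]
        return s

    def groups(self) -> list[np.ndarray]:
        """Replicate responses per concentration group (control first)."""
        order = np.unique(self.concentrations)
        return [self.responses[self.concentrations == c] for c in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chemical": self.chemical_id,
                "endpoint": self.endpoint,
                "concentration_uM": self.concentrations,
                "replicate": self.replicates,
                "response_pct": self.responses,
            }
        )


def _default_replicates(conc: np.ndarray) -> np.ndarray:
    rep = np.zeros(conc.size, dtype=int)
    counts: dict[float, int] = {}
    for i, c in enumerate(conc):
        counts[c] = counts.get(c, 0) + 1
        rep[i] = counts[c]
    return rep


@dataclasses.dataclass(frozen=True)
class HillFit:
    """A fitted constrained Hill curve (slope 1, bottom 100 % of control).

    ``direction == "none"`` marks a chemical that failed the significance
    gate; its ``top``/``ec50`` are NaN and carry no meaning.
    """

    chemical_id: str
    endpoint: str
    direction: Direction
    top: float  # plateau, % of control
    ec50: float  # µM
    significant: bool
    p_value: float
    rss: float = float("nan")
    bottom: float = CONTROL_LEVEL
    hill_slope: float = 1.0

    def __post_init__(self):
        if self.hill_slope != 1.0:
            raise InputError("hill_slope is fixed at 1")
        if self.bottom != CONTROL_LEVEL:
            raise InputError("bottom is fixed at 100 (control level)")
        if self.direction == "inhibitory" and not (0 <= self.top < CONTROL_LEVEL):
            raise InputError(f"{self.chemical_id}: inhibitory top must lie in [0, 100)")
        if self.direction == "stimulatory" and not self.top > CONTROL_LEVEL:
            raise InputError(f"{self.chemical_id}: stimulatory top must exceed 100")
        if self.direction != "none" and not self.ec50 > 0:
            raise InputError(f"{self.chemical_id}: ec50 must be positive")


@dataclasses.dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise confidence band for a fitted curve on a concentration grid."""

    concentrations: np.ndarray  # µM
    lower: np.ndarray  # % of control
    upper: np.ndarray  # % of control
    level: float = 0.95

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if not (conc.shape == lo.shape == hi.shape):
            raise InputError("band arrays must share one shape")
        if np.any(lo > hi + 1e-12):
            raise InputError("band lower edge exceeds upper edge")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)


# ---------------------------------------------------------------------------
# significance gate


def significance_gate(data: ResponseDataset, alpha: float = 0.05) -> tuple[float, bool]:
    """Kruskal-Wallis test across concentration groups (control included).

    Returns ``(p_value, significant)``.  A non-significant dataset must not
    be fitted; :func:`fit_hill` enforces this.  The rank-based test makes the
    gate invariant under monotone transformations of the responses.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    groups = data.groups()
    if len(groups) < 2:
        raise InputError(
            f"{data.chemical_id}: need >= 2 concentration groups (incl. control), got {len(groups)}"
        )
    if any(g.size < 2 for g in groups):
        raise InputError(f"{data.chemical_id}: every concentration group needs >= 2 replicates")
    if np.ptp(data.responses) == 0:
        # complete ties: no group separation at all
        return 1.0, False
    _, p = stats.kruskal(*groups)
    return float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# constrained Hill fit


def infer_direction(data: ResponseDataset) -> Direction:
    """Direction of effect from per-concentration mean responses.

    The sign of the most extreme deviation of a treatment mean from the
    control level decides.  Only when the strongest upward and downward
    deviations are nearly equal (within 5 % of each other) do the data
    straddle 100 with no dominant side, and the direction is ambiguous.
    """
    means = data.group_means()
    if means.empty:
        raise InputError(f"{data.chemical_id}: no non-zero concentrations")
    dev = means.to_numpy() - CONTROL_LEVEL
    up = float(dev.max(initial=0.0))
    down = float(-dev.min(initial=0.0))
    if up == 0.0 and down == 0.0:
        return "none"
    if up > 0 and down > 0 and min(up, down) >= 0.95 * max(up, down):
        raise DirectionAmbiguityError(
            f"{data.chemical_id}: mean responses straddle 100% of control "
            f"(max +{up:.3g} vs -{down:.3g}) with no dominant direction"
        )
    return "stimulatory" if up > down else "inhibitory"


def _hill(conc: np.ndarray, top: float, ec50: float) -> np.ndarray:
    return CONTROL_LEVEL + (top - CONTROL_LEVEL) * conc / (ec50 + conc)


def _rss(conc: np.ndarray, resp: np.ndarray, top: float, log_ec50: float) -> float:
    r = resp - _hill(conc, top, 10.0**log_ec50)
    return float(r @ r)


def _fit_inhibitory(conc, resp, top) -> tuple[float, float]:
    """1-D least squares over log10(EC50) with a multi-start window sweep."""
    lo, hi = _LOG_EC50_BOUNDS
    edges = np.linspace(lo, hi, _N_MULTISTART + 1)
    best = (np.inf, np.nan)
    for a, b in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            lambda x: _rss(conc, resp, top, x),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best[0]:
            best = (float(res.fun), float(res.x))
    if not np.isfinite(best[0]):
        raise FitConvergenceError("inhibitory EC50 search failed", {"rss": best[0]})
    return 10.0 ** best[1], best[0]


def _fit_stimulatory(conc, resp, top_max) -> tuple[float, float, float]:
    """2-D bounded least squares (top, log10 EC50), multi-start on log EC50."""
    lo, hi = _LOG_EC50_BOUNDS
    top_lo = CONTROL_LEVEL + 1e-6
    top_hi = max(top_max, top_lo + 1e-6)

    def resid(theta):
        top, log_ec50 = theta
        return resp - _hill(conc, top, 10.0**log_ec50)

    best = None
    for x0 in np.linspace(lo + 0.5, hi - 0.5, _N_MULTISTART):
        try:
            sol = optimize.least_squares(
                resid,
                x0=[min(top_hi, max(top_lo, resp.max())), x0],
                bounds=([top_lo, lo], [top_hi, hi]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        cost = 2 * sol.cost
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None or not best[1].success:
        raise FitConvergenceError(
            "stimulatory Hill fit did not converge",
            {"n_points": conc.size, "top_max": top_max},
        )
    cost, sol = best
    return float(sol.x[0]), 10.0 ** float(sol.x[1]), float(cost)


def fit_hill(
    data: ResponseDataset,
    alpha: float = 0.05,
    *,
    direction: Direction | None = None,
) -> HillFit:
    """Fit the constrained Hill model to a gated dataset.

    Runs the significance gate first and raises :class:`NotSignificantError`
    when it fails.  For inhibitory data the plateau is fixed at the minimum
    per-concentration mean response; for stimulatory data it is estimated,
    bounded above by the maximum per-concentration mean.
    """
    p, significant = significance_gate(data, alpha)
    if not significant:
        raise NotSignificantError(
            f"{data.chemical_id} / {data.endpoint}: Kruskal-Wallis p = {p:.3g} >= {alpha}; "
            "no dose-response fit is established for non-significant data"
        )
    if direction is None:
        direction = infer_direction(data)
    if direction == "none":
        raise DirectionAmbiguityError(f"{data.chemical_id}: no deviation from control")
    conc = data.concentrations
    resp = data.responses
    means = data.group_means()
    if direction == "inhibitory":
        top = float(means.min())
        top = min(top, CONTROL_LEVEL - 1e-9)  # plateau strictly below control
        ec50, rss = _fit_inhibitory(conc, resp, top)
    else:
        top_max = float(means.max())
        top, ec50, rss = _fit_stimulatory(conc, resp, top_max)
    return HillFit(
        chemical_id=data.chemical_id,
        endpoint=data.endpoint,
        direction=direction,
        top=top,
        ec50=ec50,
        significant=True,
        p_value=p,
        rss=rss,
    )


def evaluate_dataset(data: ResponseDataset, alpha: float = 0.05) -> HillFit:
    """Gate, then fit; a non-significant dataset yields a direction-"none" record."""
    p, significant = significance_gate(data, alpha)
    if not significant:
        return HillFit(
            chemical_id=data.chemical_id,
            endpoint=data.endpoint,
            direction="none",
            top=float("nan"),
            ec50=float("nan"),
            significant=False,
            p_value=p,
        )
    return fit_hill(data, alpha)


# ---------------------------------------------------------------------------
# forward / inverse evaluation


def hill_effect(fit: HillFit, concentration):
    """Effect (% of control) at a concentration (µM); vectorised.

    E(0) = 100, E(EC50) = (100 + top)/2, E(inf) = top.
    """
    _require_fitted(fit)
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise InputError(f"{fit.chemical_id}: negative concentration")
    with np.errstate(invalid="ignore"):
        e = np.where(np.isinf(c), fit.top, _hill(c, fit.top, fit.ec50))
    return float(e) if np.isscalar(concentration) or e.ndim == 0 else e


def inverse_hill(fit: HillFit, effect: float) -> float:
    """Concentration (µM) at which the chemical alone exerts ``effect``.

    Closed form c = EC50 * (e - 100)/(top - e), valid only for effects
    strictly between the control level and the plateau.  Requests beyond the
    plateau raise :class:`EffectRangeError` — for partial-efficacy chemicals
    this is what truncates the concentration-addition prediction.
    """
    _require_fitted(fit)
    e = float(effect)
    lo, hi = sorted((CONTROL_LEVEL, fit.top))
    if not lo < e < hi:
        raise EffectRangeError(
            f"{fit.chemical_id}: effect {e:g}% of control is outside the open "
            f"predictable range ({lo:g}, {hi:g}) of this chemical"
        )
    return fit.ec50 * (e - CONTROL_LEVEL) / (fit.top - e)


def _require_fitted(fit: HillFit) -> None:
    if fit.direction == "none" or not np.isfinite(fit.ec50):
        raise InputError(f"{fit.chemical_id}: fit has direction 'none'; curve is undefined")


# ---------------------------------------------------------------------------
# confidence band


def _refit_like(fit: HillFit, data: ResponseDataset, resp: np.ndarray) -> tuple[float, float]:
    """Refit (top, ec50) on perturbed responses keeping the original direction."""
    means = pd.Series(resp).groupby(data.concentrations).mean()
    means = means[means.index > 0]
    if fit.direction == "inhibitory":
        top = min(float(means.min()), CONTROL_LEVEL - 1e-9)
        ec50, _ = _fit_inhibitory(data.concentrations, resp, top)
        return top, ec50
    top, ec50, _ = _fit_stimulatory(data.concentrations, resp, float(means.max()))
    return top, ec50


def confidence_band(
    fit: HillFit,
    data: ResponseDataset,
    grid: Sequence[float],
    level: float = 0.95,
    *,
    method: Literal["bootstrap", "delta"] = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
) -> ConfidenceBand:
    """Pointwise confidence band for the fitted curve.

    Default is a residual bootstrap: residuals are resampled with
    replacement, added back to the fitted values, the constrained model is
    refitted and pointwise quantiles of the refitted curves are taken.  The
    band is widened, if needed, to contain the fitted curve itself.  A
    delta-method band (linearised standard error) is available for speed.
    """
    _require_fitted(fit)
    if not 0 < level < 1:
        raise InputError("level must lie in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    fitted_grid = np.asarray(hill_effect(fit, grid), dtype=float)
    fitted_data = _hill(data.concentrations, fit.top, fit.ec50)
    residuals = data.responses - fitted_data

    if method == "delta":
        lower, upper = _delta_band(fit, data, grid, level, residuals)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        curves = np.empty((n_boot, grid.size))
        failures = 0
        for b in range(n_boot):
            resampled = rng.choice(residuals, size=residuals.size, replace=True)
            resp = np.clip(fitted_data + resampled, 1e-6, None)
            try:
                top_b, ec50_b = _refit_like(fit, data, resp)
            except (FitConvergenceError, InputError):
                failures += 1
                curves[b] = np.nan
                continue
            curves[b] = _hill(grid, top_b, ec50_b)
        if failures > 0.2 * n_boot:
            raise FitConvergenceError(
                f"bootstrap refit failure rate {failures / n_boot:.0%} exceeds 20%",
                {"failures": failures, "n_boot": n_boot},
            )
        q = (1 - level) / 2
        lower = np.nanquantile(curves, q, axis=0)
        upper = np.nanquantile(curves, 1 - q, axis=0)
    else:
        raise InputError(f"unknown band method {method!r}")

    # pointwise band must contain the fitted curve
    lower = np.minimum(lower, fitted_grid)
    upper = np.maximum(upper, fitted_grid)
    return ConfidenceBand(concentrations=grid, lower=lower, upper=upper, level=level)


def _delta_band(fit, data, grid, level, residuals):
    """Linearised pointwise band from the residual variance and the Jacobian."""
    n = residuals.size
    n_par = 1 if fit.direction == "inhibitory" else 2
    dof = max(n - n_par, 1)
    s2 = float(residuals @ residuals) / dof

    def curve(theta, c):
        if n_par == 1:
            return _hill(c, fit.top, 10.0 ** theta[0])
        return _hill(c, theta[0], 10.0 ** theta[1])

    theta0 = np.array([np.log10(fit.ec50)]) if n_par == 1 else np.array([fit.top, np.log10(fit.ec50)])
    eps = 1e-6

    def jac(c):
        J = np.empty((np.asarray(c).size, n_par))
        base = curve(theta0, c)
        for j in range(n_par):
            t = theta0.copy()
            t[j] += eps
            J[:, j] = (curve(t, c) - base) / eps
        return J

    Jd = jac(data.concentrations)
    JtJ = Jd.T @ Jd
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
    Jg = jac(grid)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Jg, cov, Jg), 0.0))
    z = stats.t.ppf(0.5 + level / 2, dof)
    center = curve(theta0, grid)
    return center - z * se, center + z * se
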