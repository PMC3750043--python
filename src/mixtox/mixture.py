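"""Fixed-ratio mixture effect prediction: CA, IA and GCA.

Three reference models predict the effect of a fixed-ratio chemical mixture
from single-chemical Hill fits:

* **Concentration addition** (CA, Loewe additivity) — the mixture behaves
  like a dilution of one chemical.  The total mixture concentration X at
  which effect e occurs solves ``sum_i p_i * X / x_i(e) = 1``, i.e.
  ``X(e) = 1 / sum_i (p_i / x_i(e))`` with ``x_i(e)`` the concentration at
  which chemical i alone exerts e.  CA can only reach effects within every
  component's own range, so the least efficacious component's plateau bounds
  the predictable range ("partial-efficacy truncation").
* **Independent action** (IA, Bliss independence) — unaffected fractions
  multiply: ``E(X) = 100 * prod_i e_i(p_i X)/100``.  Valid for inhibition
  only; with stimulatory (>100 %) components the product loses its
  probabilistic meaning and the predictor refuses.
* **Generalized concentration addition** (GCA) — admits partial agonists
  and, with all Hill slopes fixed at 1, gives the closed form

      E(X) = (100 + sum_i top_i * p_i X / EC50_i) / (1 + sum_i p_i X / EC50_i)

  which predicts a full curve down to an efficacy-weighted asymptote.

None of the models applies when effective components have opposing
directions; :func:`check_applicability` encodes that rule.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .doseresponse import CONTROL_LEVEL, HillFit, hill_effect, inverse_hill
from .errors import EffectRangeError, InputError, NotApplicableError

MODELS = ("CA", "IA", "GCA")


@dataclasses.dataclass(frozen=True)
class MixtureComponent:
    chemical_id: str
    mass_fraction: float
    molecular_weight: float | None = None  # g/mol


@dataclasses.dataclass(frozen=True)
class MixtureDefinition:
    """A fixed-ratio mixture: component fractions sum to ~1.

    Fractions are by weight as mixtures are commonly prepared; whether they
    are interpreted as shares of the total *molar* mixture concentration or
    first converted with :func:`mass_to_molar` is the caller's choice.
    """

    name: str
    components: tuple[MixtureComponent, ...]

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise InputError(f"{self.name}: mixture has no components")
        ids = [c.chemical_id for c in comps]
        if len(set(ids)) != len(ids):
            raise InputError(f"{self.name}: duplicate chemical ids")
        if any(c.mass_fraction <= 0 for c in comps):
            raise InputError(f"{self.name}: mass fractions must be positive")
        total = sum(c.mass_fraction for c in comps)
        if not 0.99 <= total <= 1.01:
            raise InputError(f"{self.name}: fractions sum to {total:.4g}, outside [0.99, 1.01]")
        object.__setattr__(self, "components", comps)

    @property
    def chemical_ids(self) -> tuple[str, ...]:
        return tuple(c.chemical_id for c in self.components)

    def fraction(self, chemical_id: str) -> float:
        for c in self.components:
            if c.chemical_id == chemical_id:
                return c.mass_fraction
        raise InputError(f"{self.name}: no component {chemical_id!r}")


@dataclasses.dataclass(frozen=True)
class PredictionCurve:
    """A model's predicted effect vs total mixture concentration.

    ``effect_floor`` is the most extreme effect level the model can predict
    (a ceiling for stimulatory mixtures); ``truncated`` flags that part of
    the requested grid fell beyond it.
    """

    model: str
    concentrations: np.ndarray  # total mixture µM
    effects: np.ndarray  # % of control
    effect_floor: float
    truncated: bool

    def __post_init__(self):
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))


@dataclasses.dataclass(frozen=True)
class ApplicabilityReport:
    """Whether CA/IA/GCA may be computed for a set of effective components."""

    endpoint: str
    components: tuple[tuple[str, str], ...]  # (chemical_id, direction)
    verdict: str  # all_inhibitory | all_stimulatory | opposing | none_effective
    models_allowed: frozenset[str]


def mass_to_molar(mixture: MixtureDefinition) -> MixtureDefinition:
    """Convert weight fractions to molar fractions (requires all MWs).

    fraction_i ∝ mass_fraction_i / MW_i, renormalised to sum exactly 1.
    """
    missing = [c.chemical_id for c in mixture.components if not c.molecular_weight]
    if missing:
        raise InputError(f"{mixture.name}: missing molecular weight for {', '.join(missing)}")
    moles = np.array([c.mass_fraction / c.molecular_weight for c in mixture.components])
    molar = moles / moles.sum()
    return MixtureDefinition(
        name=f"{mixture.name} (molar)",
        components=tuple(
            MixtureComponent(c.chemical_id, float(f), c.molecular_weight)
            for c, f in zip(mixture.components, molar)
        ),
    )


def effective_components(fits: Iterable[HillFit], mixture: MixtureDefinition) -> list[HillFit]:
    """Significant fits for the mixture's components, in mixture order.

    Every component must have a fit record (possibly direction "none").
    Non-effective chemicals still occupy their share of the total mixture
    mass but contribute no effect term to any model.
    """
    by_id = {}
    for f in fits:
        by_id.setdefault(f.chemical_id, f)
    missing = [cid for cid in mixture.chemical_ids if cid not in by_id]
    if missing:
        raise InputError(f"{mixture.name}: no fit record for {', '.join(missing)}")
    return [
        by_id[cid]
        for cid in mixture.chemical_ids
        if by_id[cid].significant and by_id[cid].direction != "none"
    ]


def check_applicability(fits: Sequence[HillFit], endpoint: str = "") -> ApplicabilityReport:
    """Apply the uniform-direction rule to the effective components.

    Mixtures whose effective chemicals include both stimulatory and
    inhibitory members get verdict "opposing" and no model is allowed.
    IA additionally requires all-inhibitory components.
    """
    if endpoint == "" and fits:
        endpoint = fits[0].endpoint
    directions = {f.direction for f in fits}
    comps = tuple((f.chemical_id, f.direction) for f in fits)
    if not fits:
        return ApplicabilityReport(endpoint, comps, "none_effective", frozenset())
    if directions == {"inhibitory"}:
        return ApplicabilityReport(endpoint, comps, "all_inhibitory", frozenset(MODELS))
    if directions == {"stimulatory"}:
        return ApplicabilityReport(endpoint, comps, "all_stimulatory", frozenset({"CA", "GCA"}))
    return ApplicabilityReport(endpoint, comps, "opposing", frozenset())


def _require_allowed(fits: Sequence[HillFit], model: str) -> None:
    report = check_applicability(fits)
    if model not in report.models_allowed:
        if report.verdict == "none_effective":
            raise NotApplicableError(f"{model}: no effective components")
        if report.verdict == "opposing":
            raise NotApplicableError(
                f"{model}: effective components have opposing directions "
                f"({dict(report.components)}); no mixture model applies"
            )
        raise NotApplicableError(
            f"{model}: not applicable to {report.verdict} components "
            "(independent action on stimulatory effects loses its probabilistic meaning)"
        )


def _fractions(fits: Sequence[HillFit], mixture: MixtureDefinition) -> np.ndarray:
    return np.array([mixture.fraction(f.chemical_id) for f in fits])


# ---------------------------------------------------------------------------
# concentration addition


def ca_effect_floor(fits: Sequence[HillFit]) -> float:
    """Most extreme effect level reachable by CA/IA-style models.

    The plateau closest to the control level bounds the predictable range:
    max of tops for inhibitory components, min of tops for stimulatory.
    """
    _require_allowed(fits, "CA")
    tops = [f.top for f in fits]
    return float(max(tops) if fits[0].direction == "inhibitory" else min(tops))


def default_effect_grid(fits: Sequence[HillFit], n: int = 200) -> np.ndarray:
    """Effect levels spanning the CA-predictable range, slightly inset."""
    floor = ca_effect_floor(fits)
    if fits[0].direction == "inhibitory":
        return np.linspace(99.5, floor + 0.5, n)
    return np.linspace(100.5, floor - 0.5, n)


def ca_predict(
    fits: Sequence[HillFit],
    mixture: MixtureDefinition,
    effect_grid: Sequence[float] | None = None,
) -> PredictionCurve:
    """Concentration-addition prediction over a grid of effect levels.

    Effect levels beyond any component's plateau are excluded from the curve
    and flagged via ``truncated`` — partial-efficacy components shorten the
    predictable range.
    """
    _require_allowed(fits, "CA")
    p = _fractions(fits, mixture)
    floor = ca_effect_floor(fits)
    grid = default_effect_grid(fits) if effect_grid is None else np.asarray(effect_grid, dtype=float)
    concs, effects = [], []
    truncated = False
    for e in grid:
        try:
            x = np.array([inverse_hill(f, e) for f in fits])
        except EffectRangeError:
            truncated = True
            continue
        concs.append(1.0 / float(np.sum(p / x)))
        effects.append(float(e))
    if not concs:
        raise NotApplicableError("CA: no requested effect level lies inside the predictable range")
    order = np.argsort(concs)
    return PredictionCurve(
        model="CA",
        concentrations=np.asarray(concs)[order],
        effects=np.asarray(effects)[order],
        effect_floor=floor,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# independent action


def default_concentration_grid(n: int = 200) -> np.ndarray:
    """Total-mixture concentration grid, log-spaced over 1e-3 to 1e3 µM."""
    return np.logspace(-3, 3, n)


def ia_predict(
    fits: Sequence[HillFit],
    mixture: MixtureDefinition,
    conc_grid: Sequence[float] | None = None,
) -> PredictionCurve:
    """Independent-action (Bliss) prediction; inhibitory components only.

    At total concentration X each component is present at p_i * X and the
    unaffected fractions multiply.
    """
    _require_allowed(fits, "IA")
    p = _fractions(fits, mixture)
    grid = default_concentration_grid() if conc_grid is None else np.asarray(conc_grid, dtype=float)
    surv = np.ones_like(grid)
    for f, pi in zip(fits, p):
        surv = surv * np.asarray(hill_effect(f, pi * grid)) / CONTROL_LEVEL
    floor = CONTROL_LEVEL * float(np.prod([f.top / CONTROL_LEVEL for f in fits]))
    return PredictionCurve(
        model="IA",
        concentrations=grid,
        effects=CONTROL_LEVEL * surv,
        effect_floor=floor,
        truncated=False,
    )


# ---------------------------------------------------------------------------
# generalized concentration addition


def gca_predict(
    fits: Sequence[HillFit],
    mixture: MixtureDefinition,
    conc_grid: Sequence[float] | None = None,
) -> PredictionCurve:
    """Generalized concentration addition; full-range, never truncated.

    Requires every fit's Hill slope to be 1 (guaranteed by the constrained
    fit) and a uniform direction (applicability rule).
    """
    _require_allowed(fits, "GCA")
    p = _fractions(fits, mixture)
    grid = default_concentration_grid() if conc_grid is None else np.asarray(conc_grid, dtype=float)
    potency = np.array([pi / f.ec50 for f, pi in zip(fits, p)])  # p_i / EC50_i
    num = CONTROL_LEVEL + np.sum(potency[:, None] * np.array([f.top for f in fits])[:, None] * grid[None, :], axis=0)
    den = 1.0 + np.sum(potency[:, None] * grid[None, :], axis=0)
    return PredictionCurve(
        model="GCA",
        concentrations=grid,
        effects=num / den,
        effect_floor=gca_asymptote(fits, mixture),
        truncated=False,
    )


def gca_asymptote(fits: Sequence[HillFit], mixture: MixtureDefinition) -> float:
    """High-concentration limit of the GCA curve.

    The efficacy-weighted mean of component plateaus, weights p_i / EC50_i:
    lim E(X) = sum_i (p_i/EC50_i) top_i / sum_i (p_i/EC50_i).
    """
    _require_allowed(fits, "GCA")
    p = _fractions(fits, mixture)
    w = np.array([pi / f.ec50 for f, pi in zip(fits, p)])
    tops = np.array([f.top for f in fits])
    return float(np.sum(w * tops) / np.sum(w))
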