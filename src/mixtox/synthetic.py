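"""Synthetic H295R-style concentration-response data and the truth registry.

The raw replicate data behind the reference EC50/Emax values for the two
fixed-ratio mixtures (a 12-chemical human-exposure-ratio mixture and a
5-pesticide potency-adjusted mixture, characterised in the H295R
steroidogenesis assay) were never deposited.  This module therefore carries
a registry of every reported EC50/Emax pair as immutable
:class:`TruthRecord` objects, and generators that emulate the assay design:
triplicate responses at seven half-log concentrations from 0.04 to 30 µM,
Hill-shaped truth with slope 1, additive Gaussian noise on the % of control
scale.

``generate_mixture`` draws experimental-mixture data from a chosen ground
truth model (CA, IA or GCA); an ``antagonism_shift`` > 1 multiplies the
concentration axis, emulating a mixture that needs a higher total
concentration than predicted — the signature of antagonism.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Literal, Sequence

import numpy as np

from .doseresponse import CONTROL_LEVEL, HillFit, ResponseDataset, hill_effect
from .errors import InputError, NotApplicableError
from .mixture import (
    MixtureDefinition,
    ca_effect_floor,
    ca_predict,
    check_applicability,
    gca_predict,
    ia_predict,
)

#: default assay design: 7 half-log concentrations spanning 0.04-30 µM
DEFAULT_CONCENTRATIONS = tuple(np.logspace(math.log10(0.04), math.log10(30.0), 7))
DEFAULT_N_REP = 3
#: response floor (% of control): measured hormone levels cannot be <= 0
RESPONSE_FLOOR = 0.01


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """One reported single-chemical (or whole-mixture) dose-response fit.

    ``context`` names the mixture experiment the value was reported in
    ("mixture1" / "mixture2"); ``assay`` the hormone readout (LC-MS/MS or
    DELFIA).  Chemicals with no significant effect carry direction "none"
    and NaN parameters.  Where two irreconcilable fits were reported for the
    same chemical/endpoint both are stored, distinguished by ``note``.
    """

    chemical_id: str
    endpoint: str
    direction: Literal["inhibitory", "stimulatory", "none"]
    top: float  # Emax, % of control
    ec50: float  # µM
    context: str
    assay: str = "delfia"
    note: str = ""
    source: str = "reported"


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the % of control scale.

    ``proportional=True`` scales the SD with the expected response level
    (sd is then interpreted as a percentage of that level).  The same seed
    always yields the same dataset.
    """

    sd: float = 10.0
    seed: int = 0
    proportional: bool = False
    kind: str = "additive_normal"

    def __post_init__(self):
        if self.sd < 0:
            raise InputError("noise sd must be >= 0")
        if self.kind != "additive_normal":
            raise InputError(f"unknown noise kind {self.kind!r}")


def _r(chem, endpoint, direction, top, ec50, context, assay="delfia", note=""):
    return TruthRecord(chem, endpoint, direction, top, ec50, context, assay, note)


def _none(chem, endpoint, context, assay="delfia", note=""):
    return TruthRecord(chem, endpoint, "none", float("nan"), float("nan"), context, assay, note)


_REGISTRY: tuple[TruthRecord, ...] = (
    # ---- Mixture 1 whole-mixture screen across the steroidogenesis cascade (LC-MS/MS)
    _r("Mixture 1", "progesterone", "stimulatory", 1200, 16, "mixture1", "lcms", "tentative Emax; plateau not reached"),
    _none("Mixture 1", "17-OH-progesterone", "mixture1", "lcms"),
    _r("Mixture 1", "cortisol", "inhibitory", 18, 1.5, "mixture1", "lcms"),
    _r("Mixture 1", "dehydroepiandrosterone", "inhibitory", 17, 0.43, "mixture1", "lcms"),
    _r("Mixture 1", "androstenedione", "inhibitory", 9, 1.5, "mixture1", "lcms"),
    _none("Mixture 1", "estrone", "mixture1", "lcms"),
    _r("Mixture 1", "testosterone", "inhibitory", 16, 2.4, "mixture1", "lcms"),
    # ---- Mixture 1 and constituents, progesterone (DELFIA)
    _r("DDE", "progesterone", "inhibitory", 18, 0.002, "mixture1", note="modelled dataset"),
    _r("DDE", "progesterone", "inhibitory", 16, 14, "mixture1", note="independent dataset"),
    _r("prochloraz", "progesterone", "stimulatory", 2200, 0.30, "mixture1"),
    _r("Mixture 1", "progesterone", "stimulatory", 770, 10, "mixture1"),
    _none("BPA", "progesterone", "mixture1"),
    _none("butylparaben", "progesterone", "mixture1"),
    _none("DBP", "progesterone", "mixture1"),
    _none("DEHP", "progesterone", "mixture1"),
    _none("epoxiconazole", "progesterone", "mixture1"),
    _none("linuron", "progesterone", "mixture1"),
    _none("4-MBC", "progesterone", "mixture1"),
    _none("OMC", "progesterone", "mixture1"),
    _none("procymidone", "progesterone", "mixture1"),
    _none("vinclozolin", "progesterone", "mixture1"),
    # ---- Mixture 1 and constituents, testosterone (DELFIA)
    _r("BPA", "testosterone", "inhibitory", 20, 3.5, "mixture1"),
    _r("epoxiconazole", "testosterone", "inhibitory", 21, 1.5, "mixture1"),
    _r("linuron", "testosterone", "inhibitory", 58, 13, "mixture1"),
    _r("OMC", "testosterone", "inhibitory", 60, 3.4, "mixture1"),
    _r("prochloraz", "testosterone", "inhibitory", 9, 0.04, "mixture1"),
    _r("Mixture 1", "testosterone", "inhibitory", 20, 0.6, "mixture1"),
    _none("butylparaben", "testosterone", "mixture1"),
    _none("DBP", "testosterone", "mixture1"),
    _none("DDE", "testosterone", "mixture1"),
    _none("DEHP", "testosterone", "mixture1"),
    _none("4-MBC", "testosterone", "mixture1"),
    _none("procymidone", "testosterone", "mixture1"),
    _none("vinclozolin", "testosterone", "mixture1"),
    # ---- Mixture 1 and constituents, estradiol (DELFIA)
    _r("BPA", "estradiol", "stimulatory", 230, 6.6, "mixture1"),
    _r("linuron", "estradiol", "stimulatory", 127, 4.0, "mixture1"),
    _r("procymidone", "estradiol", "stimulatory", 146, 11, "mixture1"),
    _r("4-MBC", "estradiol", "stimulatory", 134, 3.5, "mixture1", note="not reproducible; considered a chance finding"),
    _r("epoxiconazole", "estradiol", "inhibitory", 45, 0.8, "mixture1"),
    _r("prochloraz", "estradiol", "inhibitory", 78, 0.13, "mixture1"),
    _none("butylparaben", "estradiol", "mixture1"),
    _none("DBP", "estradiol", "mixture1"),
    _none("DDE", "estradiol", "mixture1"),
    _none("DEHP", "estradiol", "mixture1", note="non-monotonic in one run, absent in an independent run"),
    _none("OMC", "estradiol", "mixture1"),
    _none("vinclozolin", "estradiol", "mixture1"),
    _none("Mixture 1", "estradiol", "mixture1"),
    # ---- Mixture 2 and constituents, progesterone (DELFIA)
    _r("tebuconazole", "progesterone", "inhibitory", 44, 0.13, "mixture2"),
    _r("prochloraz", "progesterone", "stimulatory", 465, 0.27, "mixture2"),
    _r("Mixture 2", "progesterone", "stimulatory", 255, 6.3, "mixture2"),
    _none("mancozeb", "progesterone", "mixture2"),
    _none("procymidone", "progesterone", "mixture2"),
    _none("epoxiconazole", "progesterone", "mixture2", note="abnormally high control level"),
    # ---- Mixture 2 and constituents, testosterone (DELFIA)
    _r("epoxiconazole", "testosterone", "inhibitory", 8, 1.0, "mixture2"),
    _r("procymidone", "testosterone", "inhibitory", 16, 3.4, "mixture2"),
    _r("prochloraz", "testosterone", "inhibitory", 1, 0.011, "mixture2"),
    _r("tebuconazole", "testosterone", "inhibitory", 44, 0.011, "mixture2"),
    _r("Mixture 2", "testosterone", "inhibitory", 12, 0.28, "mixture2"),
    _none("mancozeb", "testosterone", "mixture2"),
    # ---- Mixture 2 and constituents, estradiol (DELFIA)
    _r("epoxiconazole", "estradiol", "inhibitory", 8, 0.48, "mixture2"),
    _r("prochloraz", "estradiol", "inhibitory", 1, 0.044, "mixture2"),
    _r("tebuconazole", "estradiol", "inhibitory", 41, 4.0, "mixture2"),
    _r("Mixture 2", "estradiol", "inhibitory", 12, 1.1, "mixture2"),
    _r("mancozeb", "estradiol", "stimulatory", 284, 5.7, "mixture2"),
    _r("procymidone", "estradiol", "stimulatory", 278, 8.0, "mixture2"),
)


def truth_registry() -> tuple[TruthRecord, ...]:
    """The complete, immutable registry of reported EC50/Emax values."""
    return _REGISTRY


def find_truths(
    chemical_id: str | None = None,
    endpoint: str | None = None,
    context: str | None = None,
    assay: str | None = None,
) -> list[TruthRecord]:
    """All registry records matching the given filters."""
    out = []
    for r in _REGISTRY:
        if chemical_id is not None and r.chemical_id != chemical_id:
            continue
        if endpoint is not None and r.endpoint != endpoint:
            continue
        if context is not None and r.context != context:
            continue
        if assay is not None and r.assay != assay:
            continue
        out.append(r)
    return out


def lookup_truth(chemical_id: str, endpoint: str, context: str, assay: str | None = None) -> TruthRecord:
    """Exactly one matching record, or an error naming the ambiguity."""
    hits = find_truths(chemical_id, endpoint, context, assay)
    if not hits:
        raise InputError(f"no truth record for {chemical_id}/{endpoint} in {context}")
    if len(hits) > 1:
        notes = "; ".join(h.note or h.assay for h in hits)
        raise InputError(
            f"ambiguous truth records for {chemical_id}/{endpoint} in {context} ({notes}); "
            "filter by assay or use find_truths"
        )
    return hits[0]


def truth_to_fit(truth: TruthRecord) -> HillFit:
    """Treat a registry record as an exact constrained Hill fit."""
    return HillFit(
        chemical_id=truth.chemical_id,
        endpoint=truth.endpoint,
        direction=truth.direction,
        top=truth.top,
        ec50=truth.ec50,
        significant=truth.direction != "none",
        p_value=float("nan"),
        rss=0.0,
    )


# ---------------------------------------------------------------------------
# generators


def _truth_effect(truth: TruthRecord, conc: np.ndarray) -> np.ndarray:
    if truth.direction == "none":
        return np.full_like(conc, CONTROL_LEVEL)
    return np.asarray(hill_effect(truth_to_fit(truth), conc), dtype=float)


def _apply_noise(expected: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    sd = noise.sd * expected / CONTROL_LEVEL if noise.proportional else noise.sd
    resp = expected + rng.normal(0.0, 1.0, size=expected.shape) * sd
    return np.clip(resp, RESPONSE_FLOOR, None)


def generate_single(
    truth: TruthRecord,
    concentrations: Sequence[float] | None = None,
    n_rep: int = DEFAULT_N_REP,
    noise: NoiseModel | None = None,
) -> ResponseDataset:
    """Triplicate-style synthetic dataset for one chemical, controls included."""
    if n_rep < 1:
        raise InputError("n_rep must be >= 1")
    noise = noise or NoiseModel()
    conc_levels = np.asarray(
        DEFAULT_CONCENTRATIONS if concentrations is None else concentrations, dtype=float
    )
    rng = np.random.default_rng(noise.seed)
    conc = np.concatenate([[0.0], conc_levels])
    conc_rows = np.repeat(conc, n_rep)
    rep_rows = np.tile(np.arange(1, n_rep + 1), conc.size)
    expected = _truth_effect(truth, conc_rows)
    return ResponseDataset(
        chemical_id=truth.chemical_id,
        endpoint=truth.endpoint,
        concentrations=conc_rows,
        responses=_apply_noise(expected, noise, rng),
        replicates=rep_rows,
    )


def mixture_model_effect(
    fits: Sequence[HillFit],
    mixture: MixtureDefinition,
    model: Literal["CA", "IA", "GCA"],
    concentrations: np.ndarray,
    *,
    _n_ca_levels: int = 2000,
) -> np.ndarray:
    """Model-predicted mixture effect at given total concentrations.

    CA is defined as concentration-as-a-function-of-effect, so it is
    inverted on a dense effect grid; IA and GCA are evaluated directly.
    """
    model = model.upper()
    if model == "GCA":
        return gca_predict(fits, mixture, concentrations).effects
    if model == "IA":
        return ia_predict(fits, mixture, concentrations).effects
    if model == "CA":
        floor = ca_effect_floor(fits)
        inhib = fits[0].direction == "inhibitory"
        # dense, slightly inset effect grid; CA only reaches the floor as X -> inf
        eps = abs(CONTROL_LEVEL - floor) * 1e-4
        grid = np.linspace(CONTROL_LEVEL - eps, floor + eps, _n_ca_levels) if inhib else np.linspace(
            CONTROL_LEVEL + eps, floor - eps, _n_ca_levels
        )
        curve = ca_predict(fits, mixture, grid)
        return np.interp(
            concentrations, curve.concentrations, curve.effects,
            left=CONTROL_LEVEL, right=float(curve.effects[-1]),
        )
    raise InputError(f"unknown model {model!r}")


def _toy_opposing_effect(fits, mixture, concentrations) -> np.ndarray:
    """Toy signed-log independent-action rule for opposing-direction mixtures.

    Multiplies per-chemical effect ratios e_i/100 regardless of direction
    (equivalently sums signed log-effects).  This has no standard-model
    justification; it exists only so opposing-direction scenarios can be
    simulated on request.
    """
    log_sum = np.zeros_like(concentrations, dtype=float)
    for f in fits:
        pi = mixture.fraction(f.chemical_id)
        log_sum += np.log(np.asarray(hill_effect(f, pi * concentrations)) / CONTROL_LEVEL)
    return CONTROL_LEVEL * np.exp(log_sum)


def generate_mixture(
    truths: Iterable[TruthRecord],
    mixture: MixtureDefinition,
    ground_truth_model: Literal["CA", "IA", "GCA"] = "GCA",
    antagonism_shift: float = 1.0,
    concentrations: Sequence[float] | None = None,
    n_rep: int = DEFAULT_N_REP,
    noise: NoiseModel | None = None,
    *,
    allow_opposing_toy: bool = False,
) -> ResponseDataset:
    """Synthetic experimental-mixture dataset drawn from a reference model.

    The effective (non-"none") truths define the component curves; the
    chosen model's prediction, with its concentration axis multiplied by
    ``antagonism_shift``, is the expected response.  Opposing-direction
    truths are refused unless ``allow_opposing_toy`` explicitly requests the
    non-standard signed-log rule.
    """
    if antagonism_shift < 1:
        raise InputError("antagonism_shift must be >= 1 (a fold-change of the concentration axis)")
    noise = noise or NoiseModel()
    truths = list(truths)
    endpoint = truths[0].endpoint if truths else "unknown"
    fits = [truth_to_fit(t) for t in truths if t.direction != "none"]
    report = check_applicability(fits, endpoint)
    conc_levels = np.asarray(
        DEFAULT_CONCENTRATIONS if concentrations is None else concentrations, dtype=float
    )
    conc = np.repeat(np.concatenate([[0.0], conc_levels]), n_rep)
    rep = np.tile(np.arange(1, n_rep + 1), conc_levels.size + 1)

    if report.verdict == "opposing":
        if not allow_opposing_toy:
            raise NotApplicableError(
                f"{mixture.name}/{endpoint}: opposing-direction components; no reference "
                "model applies (pass allow_opposing_toy=True for the non-standard toy rule)"
            )
        expected = _toy_opposing_effect(fits, mixture, conc / antagonism_shift)
    elif report.verdict == "none_effective":
        expected = np.full_like(conc, CONTROL_LEVEL)
    else:
        expected = mixture_model_effect(fits, mixture, ground_truth_model, conc / antagonism_shift)

    rng = np.random.default_rng(noise.seed)
    return ResponseDataset(
        chemical_id=mixture.name,
        endpoint=endpoint,
        concentrations=conc,
        responses=_apply_noise(expected, noise, rng),
        replicates=rep,
    )
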