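# Methods

## Scope and data model

`mixtox` analyses concentration–response data from steroidogenesis assays
of the H295R type: chemicals (alone or as fixed-ratio mixtures) are applied
over a concentration series, hormone output is normalised to % of the
untreated control (controls at concentration 0 define 100 %), and effects
may be inhibitory (< 100 %) or stimulatory (> 100 %). The canonical design
is triplicates at seven half-log concentrations spanning 0.04–30 µM.

## Significance gate

Because triplicates are too few to verify normality, eligibility for curve
fitting is decided by the non-parametric Kruskal–Wallis test across all
concentration groups, control included, at α = 0.05. Datasets that fail the
gate are recorded with direction "none" and excluded from every downstream
model. Being rank-based, the gate is invariant under monotone
transformations of the response. Groups in which every response is
identical carry no evidence of separation; this degenerate case returns
p = 1 rather than an undefined statistic.

## Constrained Hill fit

The model is a three-parameter logistic with two parameters frozen:

    E(c) = 100 + (top − 100) · c / (EC50 + c)

(Hill slope 1, bottom 100 % of control). The plateau ("top", the Emax) is:

- **inhibitory data** — *fixed* at the minimum per-concentration mean
  response (the strongest observed effect). Per-concentration means, not
  single replicates, are used because replicate-level extremes are noise-
  dominated.
- **stimulatory data** — estimated, bounded above by the maximum
  per-concentration mean.

Direction is the sign of the most extreme deviation of a treatment mean
from 100. When the strongest upward and downward deviations are within 5 %
of each other the data straddle the control level with no dominant side
and the fit refuses with a direction-ambiguity error.

EC50 is estimated by least squares in log10 units. The inhibitory fit is a
one-dimensional bounded minimisation over log10 EC50 ∈ (−8, 8), run over
five contiguous windows (a multi-start guard against flat stretches) with
xatol 1e-10; the stimulatory fit is a bounded two-parameter least-squares
with five log-EC50 starts. Both are deterministic given the data.

**Consequence of pinning the plateau:** the response at the highest tested
concentration falls EC50/(EC50 + c_max) short of the true asymptote, so
even on noise-free model data the fitted top is slightly conservative and
EC50 compensates by a comparable relative amount (≈ 0.5 % for EC50 0.04 µM
against a 30 µM top concentration). Parameter recovery on exact data is
therefore accurate to the plateau-sampling gap, not to machine precision.

Forward evaluation and its exact closed-form inverse
c = EC50·(e − 100)/(top − e) are provided; the inverse is defined only for
effects strictly between the control level and the plateau, and requests
beyond a plateau raise a domain error naming the chemical — this error is
what truncates concentration-addition predictions for partial-efficacy
components. Because the inverse is exact for slope-1 curves, no numerical
root fallback is needed.

## Confidence bands

The default band is a residual bootstrap: residuals about the fitted curve
are resampled with replacement, added back to the fitted values, the
constrained model is refitted (direction and pinning rule preserved), and
pointwise quantiles of the refitted curves are taken; 1000 resamples by
default, seedable, with an error raised if more than 20 % of refits fail.
The band is widened where necessary to contain the fitted curve. A
delta-method band (linearised standard errors, t quantile) is available
for speed.

Calibration: in seeded simulations (triplicates, additive SD 10, mid-design
EC50), the nominal 95 % band covers the generating curve at EC50 in ~90 %
of datasets. The shortfall from nominal is inherited from the plateau pin,
which biases the fitted top low under noise; designs whose EC50 sits at
the edge of the tested range (e.g. a 0.04 µM EC50 with 0.04 µM as the
lowest tested concentration) undercover further (~70 % observed). This is
a property of the published fitting protocol, not of the bootstrap.

## Mixture models

Fractions: mixture tables give weight fractions, and by default these are
used directly as each component's share of the total molar mixture
concentration — reproducing the source convention of mixing weight ratios
with µM totals. An explicit `mass_to_molar` conversion (fraction ∝
mass/MW, renormalised) is provided as an opt-in correction; the packaged
fixtures carry standard reference molecular weights for this purpose
(mancozeb, a polymeric dithiocarbamate, is entered at its monomer unit
mass). Non-significant components keep their share of the total mass but
contribute no effect term (equivalent to infinite EC50).

- **Concentration addition** is computed as concentration-as-a-function-of-
  effect, X(e) = 1/Σᵢ pᵢ/xᵢ(e), over a grid of effect levels (default 200
  levels from 99.5 % to 0.5 % inside the floor). Effect levels beyond any
  component's plateau are excluded and the curve flagged truncated. The
  predictable floor is the plateau closest to 100 among components (max of
  tops for inhibition, min for stimulation).
- **Independent action** multiplies unaffected fractions at per-component
  doses pᵢX. It refuses stimulatory components: with responses above 100 %
  the factors exceed 1 and the product loses its probabilistic meaning.
  Its floor is 100·Πᵢ(topᵢ/100).
- **Generalized concentration addition** uses the slope-1 closed form
  E(X) = (100 + Σᵢ topᵢ·pᵢX/EC50ᵢ)/(1 + Σᵢ pᵢX/EC50ᵢ), which is never
  truncated and tends to the potency-weighted asymptote
  Σᵢ(pᵢ/EC50ᵢ)topᵢ / Σᵢ(pᵢ/EC50ᵢ). For a single component (or any sham
  combination of copies of one chemical) both CA and GCA reduce exactly to
  that chemical's own curve, and when all plateaus are equal the two models
  coincide.

**Applicability rule:** if the effective components of a mixture include
both stimulatory and inhibitory chemicals, no model is computed — the
verdict is "opposing" and every predictor raises. All-inhibitory mixtures
allow CA, IA and GCA; all-stimulatory mixtures allow CA and GCA only.

## Contribution curves and band location

A chemical at fraction p of the mixture contributes its own fitted curve
evaluated at p·X — a rigid right-shift by 1/p in log concentration. (The
shift must be to the *right*: a chemical diluted to fraction p needs 1/p
times more total mixture to reach the same dose.)

Curves (contributions or model predictions) are located relative to a
confidence band pointwise: horizontally in log concentration at matched
effect levels where the band edges are invertible, else vertically at
matched concentrations. "Left of band" means the curve reaches a given
effect at lower total concentration than the data support — the signature
of antagonism when the curve is a model prediction. A curve is "inside"
when ≥ 95 % of evaluable points fall within the band; otherwise a side
must account for ≥ 90 % of the outside points, else the verdict is
"mixed". The ≥ 95 %-of-points rule is an operationalisation of what is, in
the source figures, a visual judgement.

## Synthetic data

The generator emulates the assay: Hill-shaped (slope 1) truth, additive
Gaussian noise on the % of control scale with default SD 10 (the magnitude
of error bars typical of triplicate steroid assays), triplicates at the
seven half-log design concentrations plus controls, fully determined by a
seed. Responses are floored at 0.01 % of control — measured hormone levels
cannot be non-positive — which slightly biases deep-inhibition means
upward, as a quantification floor does in the real assay. Mixture datasets
are drawn from a chosen reference model's prediction curve; an
`antagonism_shift` ≥ 1 multiplies the concentration axis to emulate a
mixture needing more than the predicted concentration. Opposing-direction
scenarios are refused unless a clearly-labelled toy rule (signed-log
independent action) is explicitly requested; that rule has no standard
theoretical basis and exists only to exercise the pipeline.

The built-in registry stores every reported EC50/Emax value for the two
mixtures and their constituents, including context-specific duplicates
where the same chemical was characterised in both mixture experiments and
two irreconcilable fits reported for the same dataset (DDE/progesterone:
EC50 0.002 µM vs 14 µM across independent runs); both are kept, tagged,
and lookups that would be ambiguous raise.

What the generator does *not* emulate: heteroscedastic or correlated
replicate error, plate/batch effects, cytotoxicity at high concentrations,
non-monotonic responses, and inter-experiment control drift. Passing
closed-loop tests therefore demonstrate internal consistency of the
estimation and prediction machinery under idealised noise, not performance
on real assay data.

## Known limitations

- The confidence band of an experimental mixture fit reflects only that
  dataset's sampling error. A model prediction assembled from several
  independently fitted single-chemical curves typically carries *more*
  sampling error than the mixture fit it is compared against (in the
  packaged scenario the dominant driver, prochloraz, has its EC50 at the
  bottom edge of the tested range and is estimated poorly). Full-curve
  containment of a prediction inside such a band is therefore a stringent,
  conservative check: even a correct model frequently exits the band
  somewhere along the curve, at any noise level, because the band narrows
  with the data's information while the prediction's error does not.
  Band-location verdicts are best read as evidence of gross displacement
  (antagonism/synergy), not as a calibrated goodness-of-fit test.
- The slope-1 constraint (required by the GCA closed form) misrepresents
  chemicals with strongly cooperative or multi-site dose–response shapes.
- Weight-vs-molar fraction ambiguity is exposed, not resolved: both
  conventions are available and give different predictions.
- No model is offered for opposing-direction mixtures; this is an open
  problem, not an implementation gap.

## Problem sizes used in the test suite

Simulation-based tests use 100 seeded replicates (parameter recovery,
band coverage, closed-loop prediction) with 199–200 bootstrap resamples
per band, and the CA brute-force oracle scans 10⁵ concentrations; these
sizes give stable pass/fail behaviour at desk scale.
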