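"""End-to-end synthetic reproduction pipeline.

``run_pipeline`` strings the whole analysis together on synthetic data:
registry truths -> simulate singles and experimental mixture -> significance
gate -> constrained Hill fits -> applicability verdict -> CA/IA/GCA
predictions -> contribution curves -> comparison against the experimental
mixture's 95 % confidence band.  Everything is reproducible from
(config, seed); a JSON run log echoes both.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .contribution import compare_to_band, contribution_curve
from .doseresponse import confidence_band, evaluate_dataset, fit_hill
from .errors import MixtoxError, NotApplicableError
from .io import (
    RunConfig,
    load_packaged_mixture,
    read_mixture_table,
    write_band,
    write_comparisons,
    write_contribution_curves,
    write_fit_table,
    write_mixture_table,
    write_prediction_curves,
    write_response_table,
)
from .mixture import (
    ca_predict,
    check_applicability,
    effective_components,
    gca_predict,
    ia_predict,
    mass_to_molar,
)
from .synthetic import (
    DEFAULT_CONCENTRATIONS,
    NoiseModel,
    find_truths,
    generate_mixture,
    generate_single,
)

log = logging.getLogger("mixtox")


def _resolve_mixture(spec: str):
    if spec in ("mixture1", "mixture2"):
        return load_packaged_mixture(spec)
    return read_mixture_table(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic scenario; returns a result bundle.

    Output files are written under ``config.out_dir``.  An opposing-direction
    endpoint is not an error: the applicability report records the verdict,
    no prediction files are written, and the run completes with a warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": dataclasses.asdict(config)}
    stages: list[dict] = []

    def stage(name):
        stages.append({"stage": name, "status": "ok"})
        log.info("stage: %s", name)

    mixture = _resolve_mixture(str(config.mixture))
    context = mixture.name if mixture.name in ("mixture1", "mixture2") else "mixture1"
    if config.fraction_convention == "molar":
        mixture = mass_to_molar(mixture)
    write_mixture_table(mixture, out / "mixture.csv")
    stage("mixture definition")

    # --- simulate singles from the truth registry
    seeds = np.random.SeedSequence(config.seed).generate_state(len(mixture.components) + 1)
    singles = []
    truths = []
    for comp, s in zip(mixture.components, seeds):
        truth_hits = find_truths(comp.chemical_id, config.endpoint, context)
        if not truth_hits:
            raise MixtoxError(
                f"simulate: no truth record for {comp.chemical_id}/{config.endpoint} in {context}"
            )
        truth = truth_hits[0]  # where duplicates exist the first-reported fit is used
        truths.append(truth)
        singles.append(
            generate_single(
                truth,
                noise=NoiseModel(sd=config.noise_sd, seed=int(s) % 2**31),
                n_rep=config.n_rep,
            )
        )
    stage("simulate singles")

    # --- gate + fit
    fits = [evaluate_dataset(d, alpha=config.alpha) for d in singles]
    write_fit_table(fits, out / "fits.csv")
    stage("gate and fit singles")

    effective = effective_components(fits, mixture)
    report = check_applicability(effective, config.endpoint)
    (out / "applicability.json").write_text(
        json.dumps(
            {
                "endpoint": report.endpoint,
                "components": dict(report.components),
                "verdict": report.verdict,
                "models_allowed": sorted(report.models_allowed),
            },
            indent=2,
        )
    )
    bundle["applicability"] = report
    bundle["fits"] = fits
    stage("applicability")

    if report.verdict in ("opposing", "none_effective"):
        log.warning(
            "%s/%s: verdict %s — no predictions computed",
            mixture.name, config.endpoint, report.verdict,
        )
        bundle["predictions"] = {}
        _write_log(out, config, stages, report.verdict)
        return bundle

    # --- simulate the experimental mixture and fit it
    mix_data = generate_mixture(
        truths,
        mixture,
        ground_truth_model=config.truth_model,
        antagonism_shift=config.antagonism_shift,
        n_rep=config.n_rep,
        noise=NoiseModel(sd=config.noise_sd, seed=int(seeds[-1]) % 2**31),
    )
    write_response_table(singles + [mix_data], out / "responses.csv")
    mix_fit = fit_hill(mix_data, alpha=config.alpha)
    stage("simulate and fit experimental mixture")

    # band over the tested range; curves on a denser grid for comparison
    band_grid = np.logspace(
        np.log10(DEFAULT_CONCENTRATIONS[0]), np.log10(DEFAULT_CONCENTRATIONS[-1]), 50
    )
    grid = np.logspace(-3, 3, 200)
    band = confidence_band(
        mix_fit,
        mix_data,
        band_grid,
        method=config.band_method,
        n_boot=config.band_resamples,
        seed=config.seed,
    )
    write_band(band, out / "experimental_band.csv")
    stage("experimental confidence band")

    # --- predictions
    predictions = {}
    for model, fn in (("CA", ca_predict), ("IA", ia_predict), ("GCA", gca_predict)):
        try:
            predictions[model] = (
                fn(effective, mixture)
                if model == "CA"
                else fn(effective, mixture, grid)
            )
        except NotApplicableError as exc:
            log.warning("%s not computed: %s", model, exc)
    write_prediction_curves(predictions.values(), out / "predictions.csv")
    bundle["predictions"] = predictions
    stage("model predictions")

    # --- contributions
    contributions = [
        contribution_curve(f, mixture.fraction(f.chemical_id), grid) for f in effective
    ]
    write_contribution_curves(contributions, out / "contributions.csv")
    bundle["contributions"] = contributions
    stage("contribution curves")

    # --- compare curves to the experimental band
    comparisons = [compare_to_band(c, band) for c in predictions.values()]
    comparisons += [compare_to_band(c, band) for c in contributions]
    write_comparisons(comparisons, out / "band_comparisons.csv")
    bundle["comparisons"] = comparisons
    bundle["experimental_fit"] = mix_fit
    bundle["band"] = band
    stage("band comparison")

    _write_log(out, config, stages, report.verdict)
    return bundle


def _write_log(out: Path, config: RunConfig, stages, verdict: str) -> None:
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "mixtox_version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "seed": config.seed,
                "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
                "verdict": verdict,
                "stages": stages,
            },
            indent=2,
        )
    )
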