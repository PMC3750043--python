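"""Optional plotting: mixture panel with fit, band, predictions, contributions.

Requires matplotlib (``pip install mixtox[plots]``); nothing else in the
package imports this module.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .contribution import ContributionCurve
from .doseresponse import ConfidenceBand, HillFit, ResponseDataset, hill_effect
from .mixture import PredictionCurve

_MODEL_STYLE = {
    "CA": {"color": "tab:blue", "linestyle": ":"},
    "IA": {"color": "tab:red", "linestyle": ":"},
    "GCA": {"color": "tab:green", "linestyle": "-"},
}


def plot_mixture_panel(
    data: ResponseDataset,
    fit: HillFit | None = None,
    band: ConfidenceBand | None = None,
    predictions: Iterable[PredictionCurve] = (),
    contributions: Iterable[ContributionCurve] = (),
    ax=None,
):
    """Experimental mixture data with model predictions and contributions.

    Mean ± SD per concentration, the fitted curve with its 95 % band, the
    CA/IA/GCA prediction lines, and the shifted single-chemical contribution
    curves, on a log concentration axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = data.group_means()
    sds = (
        np.array([data.responses[data.concentrations == c].std(ddof=1) for c in means.index])
        if means.size
        else np.array([])
    )
    ax.errorbar(means.index, means.to_numpy(), yerr=sds, fmt="ko", capsize=3, label="data")
    if fit is not None:
        grid = np.logspace(np.log10(means.index.min()), np.log10(means.index.max()), 100)
        ax.plot(grid, hill_effect(fit, grid), "k-", label="fit")
    if band is not None:
        ax.plot(band.concentrations, band.lower, "k:", linewidth=1)
        ax.plot(band.concentrations, band.upper, "k:", linewidth=1, label="95% band")
    for curve in predictions:
        ax.plot(
            curve.concentrations,
            curve.effects,
            label=curve.model,
            **_MODEL_STYLE.get(curve.model, {}),
        )
    for curve in contributions:
        ax.plot(curve.concentrations, curve.effects, "--", alpha=0.5, label=curve.chemical_id)
    ax.set_xscale("log")
    ax.set_xlabel("total mixture concentration (µM)")
    ax.set_ylabel("% of control")
    ax.set_title(f"{data.chemical_id} / {data.endpoint}")
    ax.legend(fontsize=7)
    return ax
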