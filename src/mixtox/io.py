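"""Table readers/writers and run configuration.

All tables are comma-separated UTF-8 with a header row and ``.`` decimals.
Concentrations are serialised in µM and effects in % of control throughout;
log axes are a presentation-time choice only.  Floats are written with 17
significant digits so write-then-read round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .contribution import BandComparison, ContributionCurve
from .doseresponse import HillFit, ResponseDataset
from .errors import InputError
from .mixture import MixtureComponent, MixtureDefinition, PredictionCurve

_FLOAT_FMT = "%.17g"

RESPONSE_COLUMNS = ["chemical", "endpoint", "concentration_uM", "replicate", "response_pct"]
FIT_COLUMNS = ["chemical", "endpoint", "significant", "p_value", "direction", "top_pct", "ec50_uM", "rss"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    if df.empty:
        raise InputError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    s = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[s.isna() & df[column].notna()]
    if len(bad):
        # +2: header row and 1-based line numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(f"{path}: non-numeric {column} on line(s) {lines}")
    if s.isna().any():
        lines = ", ".join(str(i + 2) for i in df.index[s.isna()][:5])
        raise InputError(f"{path}: missing {column} on line(s) {lines}")
    return s


# ---------------------------------------------------------------------------
# response tables


def read_response_table(path) -> list[ResponseDataset]:
    """Read concentration-response data; one dataset per (chemical, endpoint).

    Concentration 0 rows are the untreated controls.  Malformed rows are
    reported with their line numbers.
    """
    df = _read_csv(path)
    _require_columns(df, RESPONSE_COLUMNS, path)
    conc = _numeric(df, "concentration_uM", path)
    resp = _numeric(df, "response_pct", path)
    bad = df.index[(resp <= 0) | (conc < 0)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(
            f"{path}: non-positive response_pct or negative concentration_uM on line(s) {lines}"
        )
    df = df.assign(concentration_uM=conc, response_pct=resp)
    datasets = []
    for (chem, endpoint), g in df.groupby(["chemical", "endpoint"], sort=False):
        datasets.append(
            ResponseDataset(
                chemical_id=str(chem),
                endpoint=str(endpoint),
                concentrations=g["concentration_uM"].to_numpy(),
                responses=g["response_pct"].to_numpy(),
                replicates=g["replicate"].to_numpy(dtype=int),
            )
        )
    return datasets


def write_response_table(datasets: Iterable[ResponseDataset], path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# mixture definitions


def read_mixture_table(path, name: str | None = None) -> MixtureDefinition:
    """Read a mixture definition (``chemical,mass_fraction[,molecular_weight]``).

    Warns — does not error — when the fractions sum close to but not
    exactly 1 (weight-ratio tables are often rounded to ~0.999).
    """
    df = _read_csv(path)
    _require_columns(df, ["chemical", "mass_fraction"], path)
    frac = _numeric(df, "mass_fraction", path)
    mw = None
    if "molecular_weight" in df.columns:
        mw = pd.to_numeric(df["molecular_weight"], errors="coerce")
    components = tuple(
        MixtureComponent(
            chemical_id=str(row.chemical),
            mass_fraction=float(frac[i]),
            molecular_weight=None if mw is None or pd.isna(mw[i]) else float(mw[i]),
        )
        for i, row in df.iterrows()
    )
    total = float(frac.sum())
    if abs(total - 1.0) > 1e-9:
        warnings.warn(
            f"{path}: mass fractions sum to {total:.4g}, not 1 (kept as given)",
            stacklevel=2,
        )
    return MixtureDefinition(name=name or Path(path).stem, components=components)


def load_packaged_mixture(name: str) -> MixtureDefinition:
    """Load a packaged fixed-ratio mixture fixture ("mixture1" or "mixture2")."""
    resource = importlib.resources.files("mixtox.data").joinpath(f"{name}.csv")
    if not resource.is_file():
        raise InputError(f"no packaged mixture {name!r} (expected 'mixture1' or 'mixture2')")
    with importlib.resources.as_file(resource) as p:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # the 0.999 weight-ratio sum is expected
            return read_mixture_table(p, name=name)


def write_mixture_table(mixture: MixtureDefinition, path) -> None:
    pd.DataFrame(
        {
            "chemical": [c.chemical_id for c in mixture.components],
            "mass_fraction": [c.mass_fraction for c in mixture.components],
            "molecular_weight": [c.molecular_weight for c in mixture.components],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# fit tables


def write_fit_table(fits: Iterable[HillFit], path) -> None:
    pd.DataFrame(
        {
            "chemical": [f.chemical_id for f in fits],
            "endpoint": [f.endpoint for f in fits],
            "significant": [f.significant for f in fits],
            "p_value": [f.p_value for f in fits],
            "direction": [f.direction for f in fits],
            "top_pct": [f.top for f in fits],
            "ec50_uM": [f.ec50 for f in fits],
            "rss": [f.rss for f in fits],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fit_table(path) -> list[HillFit]:
    df = _read_csv(path)
    _require_columns(df, FIT_COLUMNS, path)
    return [
        HillFit(
            chemical_id=str(r.chemical),
            endpoint=str(r.endpoint),
            direction=str(r.direction),
            top=float(r.top_pct),
            ec50=float(r.ec50_uM),
            significant=bool(r.significant),
            p_value=float(r.p_value),
            rss=float(r.rss),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# curves and comparisons


def write_prediction_curves(curves: Iterable[PredictionCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "model": c.model,
                "concentration_uM": c.concentrations,
                "effect_pct": c.effects,
                "truncated": c.truncated,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_contribution_curves(curves: Iterable[ContributionCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "chemical": c.chemical_id,
                "concentration_uM": c.concentrations,
                "effect_pct": c.effects,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_band(band, path) -> None:
    pd.DataFrame(
        {
            "concentration_uM": band.concentrations,
            "lower_pct": band.lower,
            "upper_pct": band.upper,
            "level": band.level,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_comparisons(comparisons: Iterable[BandComparison], path) -> None:
    pd.DataFrame(
        {
            "curve": [c.curve_id for c in comparisons],
            "n_points": [c.n_points for c in comparisons],
            "fraction_inside": [c.fraction_inside for c in comparisons],
            "fraction_left": [c.fraction_left for c in comparisons],
            "fraction_right": [c.fraction_right for c in comparisons],
            "verdict": [c.verdict for c in comparisons],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for the end-to-end synthetic pipeline."""

    mixture: str = "mixture1"  # packaged name or path to a mixture CSV
    endpoint: str = "testosterone"
    out_dir: str | Path = "mixtox_run"
    alpha: float = 0.05
    fraction_convention: str = "mass"  # or "molar"
    truth_model: str = "GCA"
    antagonism_shift: float = 1.0
    noise_sd: float = 10.0
    n_rep: int = 3
    seed: int = 0
    band_resamples: int = 200
    band_method: str = "bootstrap"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fraction_convention not in ("mass", "molar"):
            raise InputError("fraction_convention must be 'mass' or 'molar'")
        if self.truth_model.upper() not in ("CA", "IA", "GCA"):
            raise InputError("truth_model must be CA, IA or GCA")
        self.truth_model = self.truth_model.upper()
        if self.antagonism_shift < 1:
            raise InputError("antagonism_shift must be >= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.n_rep < 2:
            raise InputError("n_rep must be >= 2 for the significance gate")
        if int(self.seed) != self.seed or self.seed < 0:
            raise InputError("seed must be a non-negative integer")
        if self.band_method not in ("bootstrap", "delta"):
            raise InputError("band_method must be 'bootstrap' or 'delta'")
        self.out_dir = Path(self.out_dir)
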