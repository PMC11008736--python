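"""Accuracy of development-period predictions by sensor height.

For each species/plot the observed generation periods are paired with
periods predicted from the temperature series recorded at each height,
and compared with RMSE and MAE.  Heights are ranked against the 2.0 m
reference with the RMSE skill score

    RMSE_ss = 1 - RMSE_h / RMSE_ref

(the fractional RMSE improvement over predictions driven by the
reference-height series; positive iff the candidate height is strictly
better).  A table of published per-height RMSE/MAE values for the 2021
field study ships with the package for skill-score reproduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .observed import DevelopmentPeriod
from .params import SpeciesModel
from .phenology import predict_generation_periods
from .series import TemperatureSeries

logger = logging.getLogger(__name__)

REFERENCE_HEIGHT_M = 2.0


def rmse(pairs) -> float:
    """Root mean square error over (observed, predicted) day pairs."""
    obs, pred = _split(pairs)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mae(pairs) -> float:
    """Mean absolute error over (observed, predicted) day pairs."""
    obs, pred = _split(pairs)
    return float(np.mean(np.abs(obs - pred)))


def _split(pairs):
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one (observed, predicted) pair")
    return arr[:, 0], arr[:, 1]


def rmse_skill_score(rmse_h: float, rmse_ref: float) -> float:
    """1 - rmse_h / rmse_ref; positive iff the candidate beats the reference."""
    if not rmse_ref > 0:
        raise ValueError(f"reference RMSE must be positive, got {rmse_ref}")
    if rmse_h < 0:
        raise ValueError(f"RMSE cannot be negative, got {rmse_h}")
    return 1.0 - rmse_h / rmse_ref


@dataclass(frozen=True)
class HeightEvaluation:
    """Prediction-error summary for one species/plot at one sensor height."""

    species: str
    plot: str
    height_m: float
    rmse: float
    mae: float
    rmse_ss: float  # 0.0 at the reference height by construction
    n: int


def evaluate_by_height(
    observed: list[DevelopmentPeriod],
    temps: dict[float, TemperatureSeries],
    model: SpeciesModel,
    reference_height_m: float = REFERENCE_HEIGHT_M,
) -> list[HeightEvaluation]:
    """RMSE/MAE/skill score per height for one species' observed periods.

    Every observed period is re-predicted from its own start date (00:00
    local) under each height's series.  Periods whose prediction is
    incomplete at *any* height (series exhausted) are dropped at all
    heights so every height is scored on the same n; drops are logged.
    """
    if reference_height_m not in temps:
        raise ValueError(f"reference height {reference_height_m} m missing from temps")
    if not observed:
        raise ValueError("no observed periods to evaluate")
    species = observed[0].species
    plots = {p.plot for p in observed}
    if len(plots) > 1 or any(p.species != species for p in observed):
        raise ValueError("evaluate one species/plot selection at a time")
    (plot,) = plots

    starts = [p.start_date for p in observed]
    predicted = {
        h: predict_generation_periods(series, model, starts)
        for h, series in temps.items()
    }
    complete = [
        i for i in range(len(observed)) if all(predicted[h][i] is not None for h in temps)
    ]
    dropped = len(observed) - len(complete)
    if dropped:
        logger.warning(
            "%s/%s: excluded %d of %d periods with incomplete predictions",
            species, plot, dropped, len(observed),
        )
    if not complete:
        raise ValueError("no period completed at every height")

    pairs = {
        h: [(float(observed[i].days), predicted[h][i]) for i in complete] for h in temps
    }
    ref_rmse = rmse(pairs[reference_height_m])
    evals = [
        HeightEvaluation(
            species=species,
            plot=plot,
            height_m=h,
            rmse=rmse(pairs[h]),
            mae=mae(pairs[h]),
            rmse_ss=rmse_skill_score(rmse(pairs[h]), ref_rmse),
            n=len(complete),
        )
        for h in sorted(temps, reverse=True)
    ]
    return evals


def evaluations_to_frame(evals: list[HeightEvaluation], decimals: int = 2) -> pd.DataFrame:
    """Tidy frame of height evaluations rounded to reporting precision."""
    recs = [
        {
            "species": e.species,
            "plot": e.plot,
            "height_m": e.height_m,
            "rmse": round(e.rmse, decimals),
            "mae": round(e.mae, decimals),
            "rmse_ss": round(e.rmse_ss, decimals),
            "n": e.n,
        }
        for e in evals
    ]
    return pd.DataFrame.from_records(recs)


def load_reference_errors(path: str | Path | None = None) -> pd.DataFrame:
    """Published per-height RMSE/MAE table for the 2021 field study."""
    if path is None:
        src = resources.files("ricephen.data").joinpath("height_prediction_errors.csv")
        with resources.as_file(src) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def reference_skill_scores(
    height_m: float = 0.25,
    reference_height_m: float = REFERENCE_HEIGHT_M,
    errors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Skill scores recomputed from the published per-height RMSE table.

    Returns one row per species with rmse_ss_normal / rmse_ss_low (2 dp)
    for ``height_m`` against the reference height.
    """
    tab = load_reference_errors() if errors is None else errors
    out = []
    for species, grp in tab.groupby("species", sort=False):
        by_h = grp.set_index("height_m")
        row = {"species": species, "height_m": height_m}
        for plot in ("normal", "low"):
            ss = rmse_skill_score(
                float(by_h.loc[height_m, f"rmse_{plot}"]),
                float(by_h.loc[reference_height_m, f"rmse_{plot}"]),
            )
            row[f"rmse_ss_{plot}"] = round(ss, 2)
        out.append(row)
    return pd.DataFrame.from_records(out)
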