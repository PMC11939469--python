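"""Per-animal, per-period growth and intake traits.

Average daily gain (ADG) is the slope of an ordinary least-squares regression
of body weight on day; the regression coefficients give the predicted weight
at the temporal midpoint of the test (mid-test body weight, MTBW), and
metabolic body weight is the allometric scaling MBW = MTBW^0.75, the standard
proxy for maintenance energy demand.  As-fed intake is converted to a dry
matter basis with the diet's dry-matter fraction, and each animal's
dry-matter-intake (DMI) scalar is the fitted value at the window midpoint of
an OLS regression of daily DMI on day — the natural analogue of MTBW, equal
to the arithmetic mean whenever observation days are symmetric about the
midpoint.  A ``method="mean"`` switch selects the plain mean instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError
from .io import IntakeSeries, WeightSeries

logger = logging.getLogger(__name__)


@dataclass
class GrowthFit:
    """OLS fit of weight (kg) on day for one animal: slope is ADG in kg/day."""

    animal_id: str
    intercept: float
    slope: float
    resid_sd: float
    n_obs: int


def fit_growth(series: WeightSeries) -> GrowthFit:
    """Regress body weight on day; the slope is the animal's ADG (kg/day)."""
    if series.n_obs < 2 or len(np.unique(series.days)) < 2:
        raise InsufficientDataError(
            f"{series.animal_id}: need >= 2 distinct weigh days, have {series.n_obs}"
        )
    fit = sps.linregress(series.days.astype(float), series.weights_kg)
    resid = series.weights_kg - (fit.intercept + fit.slope * series.days)
    dof = series.n_obs - 2
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return GrowthFit(series.animal_id, float(fit.intercept), float(fit.slope), resid_sd, series.n_obs)


def midtest_weight(fit: GrowthFit, start_day: int, end_day: int) -> float:
    """Predicted weight at the window midpoint: intercept + slope·(start+end)/2."""
    if end_day <= start_day:
        raise ConfigurationError("end_day must exceed start_day")
    return fit.intercept + fit.slope * (start_day + end_day) / 2.0


def metabolic_weight(mtbw: float) -> float:
    """Metabolic body weight, MTBW^0.75 (kg^0.75); requires MTBW > 0."""
    mtbw = np.asarray(mtbw, dtype=float)
    if np.any(mtbw <= 0):
        raise ConfigurationError("mid-test body weight must be positive")
    out = mtbw**0.75
    return float(out) if out.ndim == 0 else out


def daily_dmi(intake: IntakeSeries, dm_fraction: float) -> pd.Series:
    """Convert as-fed intake to dry matter: each value times the DM fraction."""
    if not 0 < dm_fraction <= 1:
        raise ConfigurationError("dm_fraction must lie in (0, 1]")
    return pd.Series(intake.as_fed_kg * dm_fraction, index=pd.Index(intake.days, name="day"))


def mean_dmi(dmi: pd.Series, start_day: int, end_day: int, method: str = "midpoint") -> float:
    """The animal's DMI scalar (kg DM/day) over the test window.

    ``midpoint`` fits OLS of daily DMI on day and evaluates at the window
    midpoint; ``mean`` takes the arithmetic mean.  The two agree exactly when
    observed days are symmetric about the midpoint.
    """
    if end_day <= start_day:
        raise ConfigurationError("end_day must exceed start_day")
    if len(dmi) < 2:
        raise InsufficientDataError(f"need >= 2 intake days, have {len(dmi)}")
    if method == "mean":
        return float(dmi.mean())
    if method != "midpoint":
        raise ConfigurationError(f"unknown DMI method {method!r}")
    days = dmi.index.to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise InsufficientDataError("need >= 2 distinct intake days")
    fit = sps.linregress(days, dmi.to_numpy())
    return float(fit.intercept + fit.slope * (start_day + end_day) / 2.0)


def derive_phenotypes(
    weights: dict[str, WeightSeries],
    intakes: dict[str, IntakeSeries],
    *,
    start_day: int,
    end_day: int,
    dm_fraction: float,
    covariates: pd.DataFrame | None = None,
    dmi_method: str = "midpoint",
) -> pd.DataFrame:
    """Derive the per-animal trait table for one period.

    Returns a DataFrame with columns ``animal_id, adg, mtbw, mbw, dmi`` (plus
    any covariate columns merged on animal_id); ``rfi`` is filled later by the
    intake model.  Animals with fewer than two weight or intake observations
    are excluded with a logged reason.
    """
    rows = []
    for animal_id in sorted(set(weights) & set(intakes)):
        w, feed = weights[animal_id], intakes[animal_id]
        if w.n_obs < 2:
            logger.warning("excluding %s: only %d weight observation(s)", animal_id, w.n_obs)
            continue
        if feed.n_obs < 2:
            logger.warning("excluding %s: only %d intake observation(s)", animal_id, feed.n_obs)
            continue
        fit = fit_growth(w)
        mtbw = midtest_weight(fit, start_day, end_day)
        if mtbw <= 0:
            logger.warning("excluding %s: non-positive mid-test weight %.3f", animal_id, mtbw)
            continue
        dmi = mean_dmi(daily_dmi(feed, dm_fraction), start_day, end_day, method=dmi_method)
        rows.append(
            {
                "animal_id": animal_id,
                "adg": fit.slope,
                "mtbw": mtbw,
                "mbw": metabolic_weight(mtbw),
                "dmi": dmi,
            }
        )
    for animal_id in sorted(set(weights) ^ set(intakes)):
        logger.warning("excluding %s: present in only one of weights/intakes", animal_id)
    pheno = pd.DataFrame(rows, columns=["animal_id", "adg", "mtbw", "mbw", "dmi"])
    if covariates is not None:
        pheno = pheno.merge(covariates, on="animal_id", how="left")
    pheno["rfi"] = np.nan
    return pheno
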