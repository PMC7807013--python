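"""Breeding-phenology reconstruction and nest outcomes.

First-egg dates are observed directly, back-calculated as 32 days before
the first hatch date (the species' incubation span), or — when neither was
observed — estimated from chick wing length via a linear mixed-effects
wing-growth model calibrated on known-age chicks. Wing growth is treated
as linear only between 14 and 30 days of age. A nest is successful if at
least one chick reached an age strictly greater than 20 days; such chicks
count as fledglings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "INCUBATION_DAYS",
    "WingGrowthModel",
    "first_egg_from_hatch",
    "fit_wing_growth",
    "estimate_hatch_from_wing",
    "nest_outcome",
    "brood_condition",
    "reconstruct_nests",
]

logger = logging.getLogger(__name__)

INCUBATION_DAYS = 32          # first egg precedes first hatch by this many days
WING_AGE_MIN, WING_AGE_MAX = 14, 30
FLEDGE_AGE = 20               # success requires a chick aged strictly > 20 days

OBSERVED, BACKCALC, WING_ESTIMATED = "observed", "backcalc", "wing-estimated"


def first_egg_from_hatch(first_hatch: date) -> date:
    """First-egg date back-calculated 32 days before the first hatch date."""
    return first_hatch - timedelta(days=INCUBATION_DAYS)


@dataclass
class WingGrowthModel:
    """Linear wing growth over the 14-30 day age window.

    ``marginal_r2`` is the fixed-effects (age) share of the total marginal
    variance: var(X*beta) / (var(X*beta) + var(nest) + var(residual)).
    """

    intercept: float           # mm at age 0 (extrapolated)
    slope: float               # mm per day
    nest_re_variance: float
    residual_variance: float
    marginal_r2: float
    n_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("wing-growth slope must be positive")
        if not (0 <= self.marginal_r2 <= 1):
            raise ValueError("marginal R2 must be in [0, 1]")

    def predict_age(self, wing_mm: float) -> float:
        return (wing_mm - self.intercept) / self.slope


def fit_wing_growth(chicks: pd.DataFrame) -> WingGrowthModel:
    """Fit wing chord ~ known age with a nest random intercept (ML mixed model).

    Measurements outside the 14-30 day linear window are excluded with a
    logged count. Requires >=10 usable measurements from >=2 nests; with a
    single nest the random-effect variance is reported as 0 with a warning.
    """
    df = chicks.dropna(subset=["known_age", "wing_chord"]).copy()
    in_window = (df["known_age"] >= WING_AGE_MIN) & (df["known_age"] <= WING_AGE_MAX)
    n_excluded = int((~in_window).sum())
    if n_excluded:
        logger.info("wing growth: excluded %d measurements outside %d-%d days",
                    n_excluded, WING_AGE_MIN, WING_AGE_MAX)
    df = df[in_window]
    if len(df) < 10:
        raise ValueError(f"need >=10 in-window measurements, got {len(df)}")
    if df["known_age"].nunique() < 2:
        raise ValueError("all ages identical; slope unidentifiable")
    single_nest = df["nest_id"].nunique() < 2
    if single_nest:
        warnings.warn("single nest: random-effect variance reported as 0")
        res = smf.ols("wing_chord ~ known_age", df).fit()
        intercept, slope = res.params["Intercept"], res.params["known_age"]
        var_nest = 0.0
        var_resid = float(res.mse_resid)
    else:
        md = smf.mixedlm("wing_chord ~ known_age", df, groups=df["nest_id"])
        res = md.fit(reml=True)
        intercept = float(res.fe_params["Intercept"])
        slope = float(res.fe_params["known_age"])
        var_nest = float(res.cov_re.iloc[0, 0])
        var_resid = float(res.scale)
    fixed_pred = intercept + slope * df["known_age"].to_numpy()
    var_fixed = float(np.var(fixed_pred, ddof=0))
    r2 = var_fixed / (var_fixed + var_nest + var_resid)
    return WingGrowthModel(float(intercept), float(slope), var_nest, var_resid,
                           r2, len(df), n_excluded)


@dataclass
class WingAgeEstimate:
    age_days: float
    hatch_date: date
    first_egg_date: date
    extrapolated: bool


def estimate_hatch_from_wing(
    wing_mm: float, measured_on: date, model: WingGrowthModel
) -> WingAgeEstimate:
    """Invert the wing-growth line to age, hatch and first-egg dates.

    Uses the population-level (fixed-effects) prediction; ages are rounded
    to whole days before date arithmetic. Predicted ages outside 14-30
    days are flagged as extrapolated (growth is non-linear beyond day 30).
    """
    age = model.predict_age(wing_mm)
    extrapolated = not (WING_AGE_MIN <= age <= WING_AGE_MAX)
    if extrapolated:
        warnings.warn(f"predicted age {age:.1f} outside {WING_AGE_MIN}-{WING_AGE_MAX} "
                      "day window; estimate flagged as extrapolated")
    hatch = measured_on - timedelta(days=int(round(age)))
    return WingAgeEstimate(age, hatch, first_egg_from_hatch(hatch), extrapolated)


def nest_outcome(chick_ages: list[float | int]) -> tuple[str, int]:
    """(outcome, n_fledglings): success iff any chick aged strictly > 20 days."""
    n_fledged = sum(1 for a in chick_ages if a is not None and a > FLEDGE_AGE)
    return ("success" if n_fledged >= 1 else "failure"), n_fledged


def brood_condition(chicks: pd.DataFrame) -> float:
    """Mean over siblings of chick mass/P8; rows with P8 <= 0 are rejected."""
    df = chicks.dropna(subset=["mass", "p8"])
    bad = df["p8"] <= 0
    if bad.any():
        logger.warning("brood condition: rejected %d rows with non-positive P8",
                       int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no usable chick measurements in brood")
    return float((df["mass"] / df["p8"]).mean())


def reconstruct_nests(
    nests: pd.DataFrame,
    chicks: pd.DataFrame,
    wing_model: WingGrowthModel | None = None,
) -> pd.DataFrame:
    """Fill first-egg dates with provenance, outcomes and brood condition.

    Provenance order: observed first-egg date; else back-calculation from
    an observed first hatch date; else wing-length estimation from the
    brood's first measured chick (requires a fitted wing model).
    Returns the nest table with ``first_egg_date``, ``provenance``,
    ``outcome``, ``n_fledglings`` and ``brood_condition`` columns.
    """
    out = nests.copy()
    fed, prov = [], []
    outcomes, n_fledged, brood_cond = [], [], []
    chick_groups = dict(tuple(chicks.groupby("nest_id"))) if len(chicks) else {}
    for _, row in out.iterrows():
        nest_chicks = chick_groups.get(row["nest_id"], pd.DataFrame())
        if pd.notna(row.get("observed_first_egg")):
            fed.append(pd.Timestamp(row["observed_first_egg"]).date())
            prov.append(OBSERVED)
        elif pd.notna(row.get("observed_first_hatch")):
            fed.append(first_egg_from_hatch(pd.Timestamp(row["observed_first_hatch"]).date()))
            prov.append(BACKCALC)
        elif wing_model is not None and len(nest_chicks):
            m = nest_chicks.dropna(subset=["wing_chord", "date"]).head(1)
            if len(m):
                est = estimate_hatch_from_wing(
                    float(m["wing_chord"].iloc[0]),
                    pd.Timestamp(m["date"].iloc[0]).date(), wing_model)
                fed.append(est.first_egg_date)
                prov.append(WING_ESTIMATED)
            else:
                fed.append(pd.NaT)
                prov.append(None)
        else:
            fed.append(pd.NaT)
            prov.append(None)
        ages = (nest_chicks["age_reached"].dropna().tolist()
                if "age_reached" in nest_chicks else [])
        oc, nf = nest_outcome(ages)
        outcomes.append(oc)
        n_fledged.append(nf)
        try:
            brood_cond.append(brood_condition(nest_chicks) if len(nest_chicks) else np.nan)
        except ValueError:
            brood_cond.append(np.nan)
    out["first_egg_date"] = fed
    out["provenance"] = prov
    out["outcome"] = outcomes
    out["n_fledglings"] = n_fledged
    out["brood_condition"] = brood_cond
    return out
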