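"""Synthetic partially migratory cohort with known ground truth.

Generates the five observation tables the pipeline consumes (captures,
winter resightings, geolocator fixes, feather isotopes, nest records with
per-chick measurements) for a two-area population in which individuals
hold persistent — occasionally switching — migrant or resident strategies.

The generator emulates the statistical structure the analysis assumes:

* residents can be resighted at the colonies in winter, migrants cannot;
* geolocator tracks put residents north of 36N all winter and migrants at
  a Sahelian roost (around 14.5N) with a linear transit;
* feather d13C is bimodal, except that a fraction of migrants moult the
  sampled feather before departing and so carry the resident (Iberian)
  signature — the asymmetry that forbids calling residents from isotopes;
* body condition follows a seasonal sinusoid plus sex, area and
  individual effects, with an area-specific migrant deficit applied only
  before the pre-incubation cutoff (02 May);
* clutch sizes are underdispersed (Conway-Maxwell-Poisson) and decline
  with first-egg date; the two areas differ in mean phenology and chick
  condition.

Every observation row carries the bird/nest keys of exactly one truth row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cmp import cmp_rvs

__all__ = [
    "IsotopeParams",
    "DetectionParams",
    "PhenologyParams",
    "ClutchParams",
    "ConditionParams",
    "SimulationConfig",
    "TrueState",
    "generate_cohort",
    "generate_condition_series",
    "generate_ndvi_series",
]

AREAS = ("A-rich", "B-poor")
COLONIES = {"A-rich": ("A1",), "B-poor": ("B1", "B2", "B3")}
PRE_INCUBATION_DOY = 122  # 02 May (non-leap); deficit applies strictly before


def _check_prob(name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {v}")


def _check_pos(name: str, v: float) -> None:
    if not (v > 0):
        raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class IsotopeParams:
    """Feather d13C (permil, VPDB) generating distributions.

    Defaults put the Iberian (resident-grown) and Sahelian (migrant-grown)
    modes either side of the -20 permil cutoff; ``p_premoult`` is the
    chance a migrant's sampled feather was grown before migration and so
    carries the resident signature.
    """

    resident_mean: float = -23.5
    migrant_mean: float = -16.5
    sd: float = 1.2
    p_premoult: float = 0.15

    def __post_init__(self) -> None:
        _check_pos("isotope_params.sd", self.sd)
        _check_prob("isotope_params.p_premoult", self.p_premoult)


@dataclass(frozen=True)
class DetectionParams:
    p_winter_resight: float = 0.5    # per winter, residents only
    p_geolocator: float = 0.08       # per bird-year
    p_feather_sample: float = 0.6    # per bird-year
    p_capture: float = 0.10          # per bird-year per month
    p_senegal_sighting: float = 0.01 # rare wintering-ground resighting of a migrant

    def __post_init__(self) -> None:
        for name in ("p_winter_resight", "p_geolocator", "p_feather_sample",
                     "p_capture", "p_senegal_sighting"):
            _check_prob(f"detection_params.{name}", getattr(self, name))


@dataclass(frozen=True)
class PhenologyParams:
    """Area mean first-egg day-of-year and SD (days).

    Defaults place the rich area later (day 118 ~ 28 April) than the poor
    area (day 107 ~ 17 April), both with SD 10 days.
    """

    mean_doy: dict = field(default_factory=lambda: {"A-rich": 118.0, "B-poor": 107.0})
    sd_days: float = 10.0
    nest_fraction: float = 0.55      # bird-years initiating a monitored nest
    p_second_parent: float = 0.25    # nests whose second parent is also a cohort bird
    p_observe_first_egg: float = 0.4
    p_observe_first_hatch: float = 0.6  # of those without an observed first egg

    def __post_init__(self) -> None:
        _check_pos("phenology_params.sd_days", self.sd_days)
        for a in AREAS:
            if a not in self.mean_doy:
                raise ValueError(f"phenology_params.mean_doy missing area {a}")
        for name in ("nest_fraction", "p_second_parent", "p_observe_first_egg",
                     "p_observe_first_hatch"):
            _check_prob(f"phenology_params.{name}", getattr(self, name))


@dataclass(frozen=True)
class ClutchParams:
    """CMP clutch model: log lam = log(baseline_lam) + slope * scaled FED."""

    baseline_lam: float = 35.0
    nu: float = 2.5
    slope: float = -0.30
    hatch_prob: float = 0.85
    fledge_prob: float = 0.75

    def __post_init__(self) -> None:
        _check_pos("clutch_params.baseline_lam", self.baseline_lam)
        _check_pos("clutch_params.nu", self.nu)
        _check_prob("clutch_params.hatch_prob", self.hatch_prob)
        _check_prob("clutch_params.fledge_prob", self.fledge_prob)


@dataclass(frozen=True)
class ConditionParams:
    """Adult condition (mass/P8, g/mm) generating model.

    condition = baseline + amplitude * cos(2*pi*(doy - peak)/365)
                + sex_offset * male + area_offset * rich-area
                + individual intercept (SD individual_sd)
                - deficit[area] * (migrant and before 02 May) + noise.
    """

    baseline: float = 1.30
    amplitude: float = 0.06
    peak_doy: float = 122.0
    sex_offset: float = 0.05
    individual_sd: float = 0.04
    residual_sd: float = 0.06
    area_offset: float = 0.05
    deficit: dict = field(default_factory=lambda: {"A-rich": 0.0, "B-poor": 0.06})

    def __post_init__(self) -> None:
        _check_pos("condition_params.baseline", self.baseline)
        # zero SDs are allowed: degenerate (noise-free) configurations are
        # used to verify the generator's construction
        if self.individual_sd < 0:
            raise ValueError("condition_params.individual_sd must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("condition_params.residual_sd must be >= 0")
        for a in AREAS:
            if a not in self.deficit:
                raise ValueError(f"condition_params.deficit missing area {a}")


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 100
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    area_assignment: dict = field(default_factory=lambda: {"A-rich": 0.5, "B-poor": 0.5})
    p_migrant: float = 0.45
    p_switch: float = 0.10
    isotope_params: IsotopeParams = field(default_factory=IsotopeParams)
    detection_params: DetectionParams = field(default_factory=DetectionParams)
    phenology_params: PhenologyParams = field(default_factory=PhenologyParams)
    clutch_params: ClutchParams = field(default_factory=ClutchParams)
    condition_params: ConditionParams = field(default_factory=ConditionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if not self.years:
            raise ValueError("years must be non-empty")
        if set(self.area_assignment) != set(AREAS):
            raise ValueError(f"area_assignment must cover exactly the areas {AREAS}")
        total = sum(self.area_assignment.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"area_assignment proportions must sum to 1, got {total}")
        _check_prob("p_migrant", self.p_migrant)
        _check_prob("p_switch", self.p_switch)


@dataclass
class TrueState:
    """Ground truth: one row per bird-year, nest and individual."""

    bird_years: pd.DataFrame   # bird_id, year, area, colony, sex, age_class, strategy, cond_intercept
    nests: pd.DataFrame        # nest_id, ..., true_first_egg, clutch truth
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _doy_to_date(year: int, doy: float) -> date:
    return date(year, 1, 1) + timedelta(days=int(round(doy)) - 1)


def _draw_bird_years(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, 1)
    n = config.n_individuals
    ids = [f"B{i:04d}" for i in range(n)]
    area_names = list(config.area_assignment)
    areas = rng.choice(area_names, size=n, p=[config.area_assignment[a] for a in area_names])
    sexes = rng.choice(["female", "male"], size=n)
    colonies = [COLONIES[a][rng.integers(len(COLONIES[a]))] for a in areas]
    # a small fraction of bird-years are first-years (retained in
    # classification, excluded from fitness analyses downstream)
    cond_int = rng.normal(0.0, config.condition_params.individual_sd, size=n)
    rows = []
    for i in range(n):
        strategy = "migrant" if rng.uniform() < config.p_migrant else "resident"
        for j, year in enumerate(config.years):
            if j > 0 and rng.uniform() < config.p_switch:
                strategy = "resident" if strategy == "migrant" else "migrant"
            age_class = "first-year" if rng.uniform() < 0.07 else "adult"
            rows.append((ids[i], year, areas[i], colonies[i], sexes[i],
                         age_class, strategy, cond_int[i]))
    return pd.DataFrame(rows, columns=[
        "bird_id", "year", "area", "colony", "sex", "age_class", "strategy",
        "cond_intercept"])


def _winter_dates(rng: np.random.Generator, year: int, k: int) -> list[date]:
    """k dates uniform in [01 Nov year-1, 15 Jan year]."""
    start = date(year - 1, 11, 1)
    span = (date(year, 1, 15) - start).days
    return [start + timedelta(days=int(d)) for d in np.sort(rng.integers(0, span + 1, k))]


def _gen_resightings(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 2)
    det = config.detection_params
    rows = []
    for t in truth.itertuples():
        if t.strategy == "resident":
            if rng.uniform() < det.p_winter_resight:
                for d in _winter_dates(rng, t.year, int(rng.integers(1, 3))):
                    rows.append((t.bird_id, d.isoformat(), t.area))
        else:
            if rng.uniform() < det.p_senegal_sighting:
                d = _winter_dates(rng, t.year, 1)[0]
                rows.append((t.bird_id, d.isoformat(), "Senegal"))
    return pd.DataFrame(rows, columns=["bird_id", "date", "area"])


def _gen_fixes(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 3)
    det = config.detection_params
    rows = []
    for t in truth.itertuples():
        if rng.uniform() >= det.p_geolocator:
            continue
        start = date(t.year - 1, 10, 1)
        end = date(t.year, 2, 28)
        days = np.arange(0, (end - start).days + 1, 3)
        if t.strategy == "resident":
            lats = np.clip(rng.normal(37.2, 0.3, len(days)), 36.05, None)
            lons = rng.normal(-5.8, 0.3, len(days))
        else:
            # depart early October, ten-day linear transit to a Senegal
            # roost near 14.5N, return transit in mid February
            depart = int(rng.normal(8, 3))
            arrive = depart + 10
            back = (date(t.year, 2, 10) - start).days
            lats = np.empty(len(days))
            for i, d in enumerate(days):
                if d <= depart:
                    lats[i] = rng.normal(37.2, 0.3)
                elif d < arrive:
                    frac = (d - depart) / (arrive - depart)
                    lats[i] = 37.2 + frac * (14.5 - 37.2) + rng.normal(0, 0.5)
                elif d <= back:
                    lats[i] = np.clip(rng.normal(14.5, 1.0), None, 22.0)
                else:
                    frac = min((d - back) / 10.0, 1.0)
                    lats[i] = 14.5 + frac * (37.2 - 14.5) + rng.normal(0, 0.5)
            lons = rng.normal(-10.0, 2.0, len(days))
        for d, la, lo in zip(days, lats, lons):
            dt = start + timedelta(days=int(d))
            rows.append((t.bird_id, f"{dt.isoformat()}T12:00:00",
                         round(float(la), 4), round(float(lo), 4)))
    return pd.DataFrame(rows, columns=["bird_id", "datetime", "latitude", "longitude"])


def _gen_isotopes(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 4)
    iso = config.isotope_params
    det = config.detection_params
    rows = []
    for t in truth.itertuples():
        if rng.uniform() >= det.p_feather_sample:
            continue
        if t.strategy == "resident" or rng.uniform() < iso.p_premoult:
            v = rng.normal(iso.resident_mean, iso.sd)
        else:
            v = rng.normal(iso.migrant_mean, iso.sd)
        rows.append((t.bird_id, t.year, round(float(v), 3)))
    return pd.DataFrame(rows, columns=["bird_id", "collection_year", "d13c"])


def generate_condition_series(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Capture table: seasonal sinusoid + sex/area/individual effects +
    the area-specific migrant deficit strictly before 02 May, plus noise.

    mass and P8 are emitted so that mass/P8 equals the generated condition
    value exactly (P8 varies independently as structural size).
    """
    rng = _rng(config, 5)
    cp = config.condition_params
    det = config.detection_params
    rows = []
    for t in truth.itertuples():
        for month in range(1, 13):
            if rng.uniform() >= det.p_capture:
                continue
            day = int(rng.integers(1, 29))
            d = date(t.year, month, day)
            doy = d.timetuple().tm_yday
            c = (cp.baseline
                 + cp.amplitude * np.cos(2 * np.pi * (doy - cp.peak_doy) / 365.0)
                 + cp.sex_offset * (t.sex == "male")
                 + cp.area_offset * (t.area == "A-rich")
                 + t.cond_intercept
                 + rng.normal(0.0, cp.residual_sd))
            if t.strategy == "migrant" and doy < PRE_INCUBATION_DOY:
                c -= cp.deficit[t.area]
            p8 = rng.normal(105.0, 2.0)
            rows.append((t.bird_id, d.isoformat(), t.age_class, t.sex, t.colony,
                         t.area, round(c * p8, 3), round(rng.normal(240.0, 5.0), 1),
                         round(p8, 3), t.year))
    return pd.DataFrame(rows, columns=[
        "bird_id", "date", "age_class", "sex", "colony", "area", "mass",
        "wing_chord", "p8", "year"])


def _gen_nests(config: SimulationConfig, truth: pd.DataFrame):
    rng = _rng(config, 6)
    ph = config.phenology_params
    cl = config.clutch_params
    fed_center = float(np.mean(list(ph.mean_doy.values())))
    nest_rows, chick_rows, truth_rows = [], [], []
    nest_no = 0
    for (year, area), grp in truth.groupby(["year", "area"]):
        birds = grp["bird_id"].tolist()
        order = rng.permutation(len(birds))
        used = set()
        for idx in order:
            b = birds[idx]
            if b in used or rng.uniform() >= ph.nest_fraction:
                continue
            used.add(b)
            partner = None
            if rng.uniform() < ph.p_second_parent:
                free = [x for x in birds if x not in used]
                if free:
                    partner = free[int(rng.integers(len(free)))]
                    used.add(partner)
            nest_no += 1
            nest_id = f"N{nest_no:04d}"
            colony = grp.loc[grp["bird_id"] == b, "colony"].iloc[0]
            fed_doy = rng.normal(ph.mean_doy[area], ph.sd_days)
            fed = _doy_to_date(year, fed_doy)
            lam = cl.baseline_lam * np.exp(cl.slope * (fed_doy - fed_center) / ph.sd_days)
            clutch = int(cmp_rvs(lam, cl.nu, rng, size=(1,))[0])
            clutch = max(clutch, 1)
            hatch = fed + timedelta(days=32)
            n_hatched = int(rng.binomial(clutch, cl.hatch_prob))
            obs_fed = rng.uniform() < ph.p_observe_first_egg
            obs_hatch = (not obs_fed) and rng.uniform() < ph.p_observe_first_hatch
            for ci in range(n_hatched):
                chick_id = f"{nest_id}C{ci}"
                if rng.uniform() < cl.fledge_prob:
                    age_reached = int(rng.integers(21, 31))
                else:
                    age_reached = int(rng.integers(1, 21))
                meas_age = None
                if age_reached >= 14:
                    meas_age = int(rng.integers(14, min(30, age_reached) + 1))
                    meas_date = hatch + timedelta(days=meas_age)
                    nest_eff = rng.normal(0.0, 3.0)
                    wing = -10.0 + 5.0 * meas_age + nest_eff + rng.normal(0.0, 4.0)
                    chick_p8 = 2.0 * meas_age + 5.0 + rng.normal(0.0, 1.0)
                    base = 2.93 if area == "A-rich" else 1.86
                    sd = 1.10 if area == "A-rich" else 0.59
                    cond = max(rng.normal(base, sd), 0.3)
                    chick_rows.append((
                        nest_id, chick_id, meas_date.isoformat(),
                        round(wing, 1), round(chick_p8, 2), round(cond * chick_p8, 1),
                        meas_age if (obs_fed or obs_hatch) else None,
                        age_reached))
                else:
                    chick_rows.append((nest_id, chick_id, None, None, None, None,
                                       None, age_reached))
            nest_rows.append((
                nest_id, colony, area, year, b, partner,
                fed.isoformat() if obs_fed else None,
                hatch.isoformat() if (obs_fed or obs_hatch) and n_hatched > 0 else None,
                clutch))
            truth_rows.append((nest_id, year, area, b, partner, fed.isoformat(),
                               clutch, n_hatched))
    nests = pd.DataFrame(nest_rows, columns=[
        "nest_id", "colony", "area", "year", "parent1", "parent2",
        "observed_first_egg", "observed_first_hatch", "clutch_size"])
    chicks = pd.DataFrame(chick_rows, columns=[
        "nest_id", "chick_id", "date", "wing_chord", "p8", "mass",
        "known_age", "age_reached"])
    nest_truth = pd.DataFrame(truth_rows, columns=[
        "nest_id", "year", "area", "parent1", "parent2", "true_first_egg",
        "true_clutch", "n_hatched"])
    return nests, chicks, nest_truth


def generate_cohort(config: SimulationConfig | None = None):
    """Generate all observation tables plus ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps table name ->
    DataFrame for {captures, resightings, geolocator_fixes,
    feather_isotopes, nests, nest_chicks}. Deterministic given
    ``config.seed``; each observation stream has an independent seeded
    substream, so tables are reproducible individually as well.
    """
    config = config or SimulationConfig()
    truth = _draw_bird_years(config)
    nests, chicks, nest_truth = _gen_nests(config, truth)
    tables = {
        "captures": generate_condition_series(config, truth),
        "resightings": _gen_resightings(config, truth),
        "geolocator_fixes": _gen_fixes(config, truth),
        "feather_isotopes": _gen_isotopes(config, truth),
        "nests": nests,
        "nest_chicks": chicks,
    }
    return tables, TrueState(truth, nest_truth, config)


def generate_ndvi_series(
    n_pixels_per_area: int = 20,
    peak_doy: dict | None = None,
    amplitude: float = 0.25,
    level: dict | None = None,
    pixel_sd: float = 0.03,
    noise_sd: float = 0.05,
    dates_per_year: int = 24,
    year: int = 2016,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic NDVI pixel table: per-area seasonal sinusoid + pixel
    intercept + noise, on a regular within-year sampling grid."""
    rng = np.random.default_rng(seed)
    peak_doy = peak_doy or {"A-rich": 110.0, "B-poor": 80.0}
    level = level or {"A-rich": 0.55, "B-poor": 0.45}
    doys = np.linspace(5, 360, dates_per_year)
    rows = []
    for area in AREAS:
        for p in range(n_pixels_per_area):
            pid = f"{area[:1]}P{p:03d}"
            off = rng.normal(0.0, pixel_sd)
            for doy in doys:
                v = (level[area] + off
                     + amplitude * np.cos(2 * np.pi * (doy - peak_doy[area]) / 365.0)
                     + rng.normal(0.0, noise_sd))
                rows.append((pid, area, _doy_to_date(year, doy).isoformat(),
                             round(float(np.clip(v, -1, 1)), 4)))
    return pd.DataFrame(rows, columns=["pixel_id", "area", "date", "ndvi"])
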