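"""Bird-year migratory-strategy classification.

Each individual in each breeding year (a "bird-year") is classified as
migrant, resident or unknown from up to three evidence streams:

* winter resightings in the breeding areas (resident evidence only; a
  sighting at a known wintering ground is migrant evidence),
* geolocator position fixes (resident if no winter fix south of 36N,
  migrant if at least two winter fixes south of 23N),
* feather delta-13-C of the winter-grown P9/P10 feather (migrant if above
  the cutoff, by default -20 permil; never used to call residents, since
  some migrants moult these feathers before departing).

The winter window for breeding year Y runs 01 November of Y-1 through
15 January of Y, both ends inclusive. Streams that disagree produce an
``unknown`` call with a conflict flag rather than a silent resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "StrategyRules",
    "Evidence",
    "StrategyCall",
    "winter_year",
    "classify_by_resighting",
    "classify_by_geolocator",
    "classify_by_isotope",
    "reconcile",
    "classify_cohort",
    "calls_to_frame",
    "strategy_consistency",
    "sensitivity_analysis",
]

logger = logging.getLogger(__name__)

MIGRANT = "migrant"
RESIDENT = "resident"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class StrategyRules:
    """Thresholds of the classification rules (all overridable)."""

    window_start_month: int = 11
    window_start_day: int = 1
    window_end_month: int = 1
    window_end_day: int = 15
    resident_lat_floor: float = 36.0
    migrant_lat_ceiling: float = 23.0
    min_southern_fixes: int = 2
    isotope_cutoff: float = -20.0
    sensitivity_offsets: tuple[float, ...] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        if not self.migrant_lat_ceiling < self.resident_lat_floor:
            raise ValueError("migrant_lat_ceiling must be below resident_lat_floor")
        if not np.isfinite(self.isotope_cutoff):
            raise ValueError("isotope_cutoff must be finite")
        if self.min_southern_fixes < 1:
            raise ValueError("min_southern_fixes must be >= 1")


@dataclass(frozen=True)
class Evidence:
    stream: str          # resighting | geolocator | isotope
    verdict: str         # migrant | resident | unknown
    detail: str = ""


@dataclass
class StrategyCall:
    bird_id: str
    year: int
    strategy: str
    evidence: list[Evidence] = field(default_factory=list)
    conflict: bool = False


def winter_year(d: date, rules: StrategyRules) -> int | None:
    """Breeding year whose winter window contains ``d``, else None.

    A date on/after 01 Nov belongs to the following breeding year; a date
    on/before 15 Jan belongs to the current year. Both bounds inclusive.
    """
    start = (rules.window_start_month, rules.window_start_day)
    end = (rules.window_end_month, rules.window_end_day)
    if (d.month, d.day) >= start:
        return d.year + 1
    if (d.month, d.day) <= end:
        return d.year
    return None


def _require_dates(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], errors="coerce")
    bad = df.index[parsed.isna()]
    if len(bad):
        raise ValueError(f"{what}: undated/unparseable {col} at rows {list(bad[:10])}")
    return parsed


def classify_by_resighting(
    records: pd.DataFrame,
    rules: StrategyRules,
    breeding_areas: tuple[str, ...] = ("A-rich", "B-poor"),
) -> dict[tuple[str, int], list[Evidence]]:
    """Resident verdicts from in-area winter resightings.

    A record in one of ``breeding_areas`` dated inside the winter window
    yields a resident verdict for the following breeding season; a record
    anywhere else (a wintering-ground sighting, e.g. Senegal) yields a
    migrant verdict. Records outside the window yield nothing.
    """
    out: dict[tuple[str, int], list[Evidence]] = {}
    if records.empty:
        return out
    dates = _require_dates(records, "date", "resightings")
    for (bird, d, area) in zip(records["bird_id"], dates, records["area"]):
        year = winter_year(d.date(), rules)
        if year is None:
            continue
        if area in breeding_areas:
            ev = Evidence("resighting", RESIDENT, f"in-area {area} on {d.date()}")
        else:
            ev = Evidence("resighting", MIGRANT, f"wintering-ground {area} on {d.date()}")
        out.setdefault((str(bird), year), []).append(ev)
    return out


def classify_by_geolocator(
    fixes: pd.DataFrame, rules: StrategyRules
) -> dict[tuple[str, int], list[Evidence]]:
    """Per bird-year geolocator verdicts from winter-window latitudes.

    Resident iff every window fix is at or north of the 36N floor; migrant
    iff at least ``min_southern_fixes`` window fixes fall south of the 23N
    ceiling; anything else (fixes only at intermediate latitudes) is
    unknown. A bird-year whose track has no window fix at all is unknown
    with "no winter coverage" — absence of data is not residency evidence.
    """
    out: dict[tuple[str, int], list[Evidence]] = {}
    if fixes.empty:
        return out
    dt = _require_dates(fixes, "datetime", "geolocator fixes")
    lat = fixes["latitude"].astype(float)
    bad = fixes.index[(lat < -90) | (lat > 90)]
    if len(bad):
        raise ValueError(f"geolocator fixes: latitude out of bounds at rows {list(bad[:10])}")
    df = pd.DataFrame({"bird_id": fixes["bird_id"].astype(str), "dt": dt, "lat": lat})
    # candidate bird-years: any year whose Jul(Y-1)..Jun(Y) season the track touches
    df["season_year"] = np.where(df["dt"].dt.month >= 7, df["dt"].dt.year + 1, df["dt"].dt.year)
    df["window_year"] = [winter_year(d.date(), rules) for d in df["dt"]]
    for (bird, year), grp in df.groupby(["bird_id", "season_year"]):
        win = grp[grp["window_year"] == year]
        if win.empty:
            ev = Evidence("geolocator", UNKNOWN, "no winter coverage")
        elif (win["lat"] >= rules.resident_lat_floor).all():
            ev = Evidence("geolocator", RESIDENT,
                          f"{len(win)} window fixes, none south of {rules.resident_lat_floor}N")
        elif (win["lat"] < rules.migrant_lat_ceiling).sum() >= rules.min_southern_fixes:
            ev = Evidence("geolocator", MIGRANT,
                          f"{int((win['lat'] < rules.migrant_lat_ceiling).sum())} fixes "
                          f"south of {rules.migrant_lat_ceiling}N")
        else:
            ev = Evidence("geolocator", UNKNOWN, "intermediate latitudes")
        out.setdefault((bird, int(year)), []).append(ev)
    return out


def classify_by_isotope(
    samples: pd.DataFrame, cutoff: float
) -> dict[tuple[str, int], list[Evidence]]:
    """Migrant verdicts from feather delta-13-C.

    Migrant iff d13c strictly exceeds ``cutoff``; otherwise indeterminate
    (never resident — low values can come from pre-migration moult on the
    breeding grounds). A feather collected in breeding year Y reflects the
    winter preceding season Y.
    """
    out: dict[tuple[str, int], list[Evidence]] = {}
    if samples.empty:
        return out
    if samples["d13c"].isna().any():
        bad = samples.index[samples["d13c"].isna()]
        raise ValueError(f"isotope samples: missing d13c at rows {list(bad[:10])}")
    vals = samples["d13c"].astype(float)
    outside = samples.index[(vals < -40) | (vals > 0)]
    if len(outside):
        logger.warning("d13c outside plausibility bounds (-40..0) at rows %s",
                       list(outside[:10]))
    for bird, year, v in zip(samples["bird_id"], samples["collection_year"], vals):
        if v > cutoff:
            ev = Evidence("isotope", MIGRANT, f"d13c {v:.2f} > {cutoff:.1f}")
        else:
            ev = Evidence("isotope", UNKNOWN, f"d13c {v:.2f} <= {cutoff:.1f} (indeterminate)")
        out.setdefault((str(bird), int(year)), []).append(ev)
    return out


def reconcile(bird_id: str, year: int, evidence: list[Evidence]) -> StrategyCall:
    """Combine per-stream verdicts into one call.

    All determinate verdicts agreeing gives that strategy; none gives
    unknown; a resident-vs-migrant contradiction gives unknown with the
    conflict flag set and all evidence retained.
    """
    determinate = {ev.verdict for ev in evidence if ev.verdict != UNKNOWN}
    if not determinate:
        return StrategyCall(bird_id, year, UNKNOWN, evidence, conflict=False)
    if len(determinate) == 1:
        return StrategyCall(bird_id, year, determinate.pop(), evidence, conflict=False)
    return StrategyCall(bird_id, year, UNKNOWN, evidence, conflict=True)


def classify_cohort(
    resightings: pd.DataFrame,
    fixes: pd.DataFrame,
    isotopes: pd.DataFrame,
    rules: StrategyRules | None = None,
    breeding_areas: tuple[str, ...] = ("A-rich", "B-poor"),
    isotope_cutoff: float | None = None,
) -> list[StrategyCall]:
    """Run all three streams and reconcile every observed bird-year."""
    rules = rules or StrategyRules()
    cutoff = rules.isotope_cutoff if isotope_cutoff is None else isotope_cutoff
    merged: dict[tuple[str, int], list[Evidence]] = {}
    for stream in (
        classify_by_resighting(resightings, rules, breeding_areas),
        classify_by_geolocator(fixes, rules),
        classify_by_isotope(isotopes, cutoff),
    ):
        for key, evs in stream.items():
            merged.setdefault(key, []).extend(evs)
    return [reconcile(b, y, evs) for (b, y), evs in sorted(merged.items())]


def calls_to_frame(calls: list[StrategyCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "bird_id": [c.bird_id for c in calls],
        "year": [c.year for c in calls],
        "strategy": [c.strategy for c in calls],
        "streams": ["+".join(sorted({e.stream for e in c.evidence})) for c in calls],
        "conflict": [c.conflict for c in calls],
    })


def strategy_consistency(calls: list[StrategyCall]) -> dict:
    """Between-year strategy consistency for multi-year individuals.

    Individuals with >=2 determined bird-years are classed as consistent
    or as having switched (direction tabulated from year-ordered calls);
    single-year individuals are excluded by definition.
    """
    per_bird: dict[str, list[tuple[int, str]]] = {}
    for c in calls:
        if c.strategy in (MIGRANT, RESIDENT):
            per_bird.setdefault(c.bird_id, []).append((c.year, c.strategy))
    consistent = 0
    m_to_r = 0
    r_to_m = 0
    multi = 0
    for bird, seq in per_bird.items():
        if len(seq) < 2:
            continue
        multi += 1
        seq = sorted(seq)
        switches = [(a[1], b[1]) for a, b in zip(seq, seq[1:]) if a[1] != b[1]]
        if not switches:
            consistent += 1
        else:
            m_to_r += sum(1 for s in switches if s == (MIGRANT, RESIDENT))
            r_to_m += sum(1 for s in switches if s == (RESIDENT, MIGRANT))
    return {
        "individuals_multi_year": multi,
        "consistent": consistent,
        "migrant_to_resident": m_to_r,
        "resident_to_migrant": r_to_m,
    }


def sensitivity_analysis(
    resightings: pd.DataFrame,
    fixes: pd.DataFrame,
    isotopes: pd.DataFrame,
    rules: StrategyRules | None = None,
    breeding_areas: tuple[str, ...] = ("A-rich", "B-poor"),
) -> dict[float, list[StrategyCall]]:
    """Re-run the full classification at the shifted isotope cutoffs.

    Returns one complete call set per cutoff in {base+offset for offsets}
    plus the base cutoff, so downstream analyses can be repeated per
    variant and compared for concordance.
    """
    rules = rules or StrategyRules()
    cutoffs = sorted({rules.isotope_cutoff}
                     | {rules.isotope_cutoff + o for o in rules.sensitivity_offsets})
    out = {}
    for c in cutoffs:
        out[c] = classify_cohort(resightings, fixes, isotopes,
                                 replace(rules, isotope_cutoff=c), breeding_areas)
    return out


def migrant_counts(by_cutoff: dict[float, list[StrategyCall]]) -> dict[float, int]:
    return {c: sum(1 for call in calls if call.strategy == MIGRANT)
            for c, calls in by_cutoff.items()}
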