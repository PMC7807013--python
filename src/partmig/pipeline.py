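"""End-to-end analysis pipeline.

Orchestrates classification -> phenology -> condition -> inference on the
five observation tables (read from disk or freshly simulated), applies
the year exclusions and the one-parent-per-clutch rule, and assembles a
structured report: strategy-call summaries, per-analysis selection tables
with the Delta-2/fewest-parameters final model, post-hoc contrasts for
the pre-incubation interaction, and a row-accounting funnel so sample
sizes are auditable at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from . import condition as cond
from . import io as tio
from . import phenology as phen
from . import selection as sel
from . import strategy as strat
from .simulate import SimulationConfig, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "apply_exclusions",
           "dedupe_clutch_parents", "run_pipeline", "run_sensitivity"]

logger = logging.getLogger(__name__)

ANALYSES = ("year_round_condition", "pre_incubation_condition", "first_egg_date",
            "clutch_size", "n_fledglings", "nest_outcome", "fledging_probability",
            "chick_condition")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs, with every rule constant surfaced."""

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    rules: strat.StrategyRules = field(default_factory=strat.StrategyRules)
    breeding_areas: tuple[str, ...] = ("A-rich", "B-poor")
    pre_incubation_cutoff: tuple[int, int] = (5, 2)   # strictly before 02 May
    excluded_years: tuple[int, ...] = (2018,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("either simulation or input_dir must be given")


@dataclass
class AnalysisReport:
    strategy_counts: dict
    consistency: dict
    funnel: dict
    provenance_counts: dict
    wing_growth: dict | None
    condition_fit: dict
    selection: dict[str, sel.SelectionTable]
    posthoc: sel.PosthocResult | None
    log: list[str] = field(default_factory=list)

    def final_terms(self) -> dict[str, str]:
        return {name: tab.final.term_label for name, tab in self.selection.items()}

    def to_json(self) -> str:
        payload: dict[str, Any] = {
            "strategy_counts": self.strategy_counts,
            "consistency": self.consistency,
            "funnel": self.funnel,
            "provenance_counts": self.provenance_counts,
            "wing_growth": self.wing_growth,
            "condition_fit": self.condition_fit,
            "analyses": {
                name: tab.to_frame().to_dict(orient="records")
                for name, tab in self.selection.items()
            },
            "posthoc": (self.posthoc.to_frame().to_dict(orient="records")
                        if self.posthoc else None),
            "log": self.log,
        }
        return json.dumps(payload, indent=2, default=float)

    def to_text(self) -> str:
        lines = ["=== Strategy calls ==="]
        for k, v in self.strategy_counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("=== Consistency ===")
        for k, v in self.consistency.items():
            lines.append(f"  {k}: {v}")
        lines.append("=== Final models ===")
        for name, terms in self.final_terms().items():
            lines.append(f"  {name}: {terms}")
        if self.posthoc is not None:
            lines.append("=== Post-hoc contrasts (pre-incubation condition) ===")
            lines.append(self.posthoc.to_frame().to_string(index=False))
        lines.append("=== Funnel ===")
        for k, v in self.funnel.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def apply_exclusions(df: pd.DataFrame, excluded_years: tuple[int, ...],
                     year_col: str = "year") -> tuple[pd.DataFrame, int]:
    """Drop excluded years from an inference input; returns (kept, n_dropped).

    The exclusion applies to inference inputs only — the condition
    smoother and the wing-growth calibration keep all years.
    """
    if not excluded_years:
        return df, 0
    keep = ~df[year_col].isin(excluded_years)
    out = df[keep]
    if out.empty:
        raise RuntimeError("all rows excluded by year filter; nothing to analyse")
    return out, int((~keep).sum())


def dedupe_clutch_parents(nests: pd.DataFrame, strategy_of: dict[tuple[str, int], str],
                          seed: int) -> tuple[pd.DataFrame, dict]:
    """One known-strategy parent per clutch.

    Clutches with two known-strategy parents contribute one parent chosen
    uniformly at random (seeded); clutches with none are dropped. Returns
    the nest table with ``parent_id``/``strategy`` columns plus a summary
    of pair counts (including mixed-strategy pairs).
    """
    rng = np.random.default_rng([seed, 97])
    rows = []
    pairs = mixed = dropped = 0
    for _, r in nests.iterrows():
        year = int(r["year"])
        cands = []
        for col in ("parent1", "parent2"):
            p = r.get(col)
            if pd.notna(p) and (str(p), year) in strategy_of:
                s = strategy_of[(str(p), year)]
                if s in (strat.MIGRANT, strat.RESIDENT):
                    cands.append((str(p), s))
        if not cands:
            dropped += 1
            continue
        if len(cands) == 2:
            pairs += 1
            if cands[0][1] != cands[1][1]:
                mixed += 1
            cands = [cands[int(rng.integers(2))]]
        pid, s = cands[0]
        row = r.to_dict()
        row["parent_id"] = pid
        row["strategy"] = s
        rows.append(row)
    out = pd.DataFrame(rows)
    summary = {"known_strategy_pairs": pairs, "mixed_strategy_pairs": mixed,
               "dropped_no_strategy": dropped, "retained": len(out)}
    return out, summary


def _adult_bird_years(captures: pd.DataFrame) -> set[tuple[str, int]]:
    """Bird-years with any capture flagged below adult age are excluded
    from fitness analyses (they stay in classification)."""
    non_adult = captures[captures["age_class"] != "adult"]
    return {(str(b), int(y)) for b, y in zip(non_adult["bird_id"], non_adult["year"])}


def _load_tables(config: AnalysisConfig):
    if config.simulation is not None:
        tables, truth = generate_cohort(config.simulation)
        return tables, truth
    return tio.read_all(config.input_dir), None


def run_pipeline(config: AnalysisConfig, tables: dict[str, pd.DataFrame] | None = None,
                 calls: list[strat.StrategyCall] | None = None) -> AnalysisReport:
    """Execute the full analysis and assemble the report.

    ``tables``/``calls`` may be supplied to reuse previously generated
    inputs (the sensitivity analysis re-runs the pipeline per isotope
    cutoff on the same tables). Deterministic given config and seed.
    """
    log: list[str] = []
    funnel: dict[str, int] = {}
    if tables is None:
        tables, _ = _load_tables(config)
    for name, df in tables.items():
        funnel[f"input_rows[{name}]"] = len(df)

    # --- 1. strategy classification ------------------------------------
    if calls is None:
        calls = strat.classify_cohort(
            tables["resightings"], tables["geolocator_fixes"],
            tables["feather_isotopes"], config.rules, config.breeding_areas)
    calls_df = strat.calls_to_frame(calls)
    strategy_of = {(c.bird_id, c.year): c.strategy for c in calls}
    determined = calls_df[calls_df["strategy"] != strat.UNKNOWN]
    sex_of = (tables["captures"].drop_duplicates("bird_id")
              .set_index("bird_id")["sex"].to_dict())
    non_adult = _adult_bird_years(tables["captures"])
    adult_det = determined[
        ~determined.apply(lambda r: (r["bird_id"], r["year"]) in non_adult, axis=1)]
    strategy_counts = {
        "bird_years_classified": len(calls_df),
        "determined": len(determined),
        "unknown": int((calls_df["strategy"] == strat.UNKNOWN).sum()),
        "conflicts": int(calls_df["conflict"].sum()),
        "migrant": int((calls_df["strategy"] == strat.MIGRANT).sum()),
        "resident": int((calls_df["strategy"] == strat.RESIDENT).sum()),
        "adult_determined": len(adult_det),
        "adult_migrant": int((adult_det["strategy"] == strat.MIGRANT).sum()),
        "adult_resident": int((adult_det["strategy"] == strat.RESIDENT).sum()),
    }
    for s in (strat.MIGRANT, strat.RESIDENT):
        sub = adult_det[adult_det["strategy"] == s]
        sexes = sub["bird_id"].map(sex_of).value_counts().to_dict()
        strategy_counts[f"adult_{s}_by_sex"] = sexes
    consistency = strat.strategy_consistency(calls)
    funnel["strategy_calls"] = len(calls_df)
    funnel["strategy_determined"] = len(determined)

    # --- 2. phenology reconstruction ------------------------------------
    chicks = tables["nest_chicks"]
    wing_model = None
    wing_info = None
    known = chicks.dropna(subset=["known_age", "wing_chord"]) if len(chicks) else chicks
    if len(known) >= 10:
        wing_model = phen.fit_wing_growth(chicks)
        wing_info = {"slope": wing_model.slope, "intercept": wing_model.intercept,
                     "marginal_r2": wing_model.marginal_r2, "n": wing_model.n_used}
    else:
        log.append("wing-growth model skipped (insufficient known-age chicks)")
    nests = phen.reconstruct_nests(tables["nests"], chicks, wing_model)
    provenance_counts = nests["provenance"].value_counts(dropna=False).to_dict()
    provenance_counts = {str(k): int(v) for k, v in provenance_counts.items()}

    # --- 3. condition index (all years, adults) -------------------------
    adults = tables["captures"][tables["captures"]["age_class"] == "adult"].copy()
    smooth = cond.fit_condition_smooth(adults)
    adults = adults.assign(relative_condition=smooth.residuals)
    condition_fit = {
        "n_captures": smooth.n, "edf": smooth.edf,
        "bird_intercept_sd": smooth.random_intercept_sd,
        "residual_sd": smooth.residual_sd, "sex_offset": smooth.sex_offset,
    }
    funnel["adult_captures_smoothed"] = smooth.n

    # --- 4. inference datasets (excluded years dropped) ------------------
    adults["strategy"] = [strategy_of.get((str(b), int(y)))
                          for b, y in zip(adults["bird_id"], adults["year"])]
    cond_rows = adults[adults["strategy"].isin([strat.MIGRANT, strat.RESIDENT])].copy()
    cond_rows = cond_rows[~cond_rows.apply(
        lambda r: (str(r["bird_id"]), int(r["year"])) in non_adult, axis=1)]
    cond_rows["doy"] = pd.to_datetime(cond_rows["date"]).dt.dayofyear.astype(float)
    cond_rows, n_dropped = apply_exclusions(cond_rows, config.excluded_years)
    funnel["condition_rows_used"] = len(cond_rows)
    funnel["condition_rows_excluded_by_year"] = n_dropped

    pre_rows = cond.pre_incubation_subset(cond_rows, config.pre_incubation_cutoff)
    funnel["pre_incubation_rows"] = len(pre_rows)

    nests_a, pair_summary = dedupe_clutch_parents(nests, strategy_of, config.seed)
    funnel.update({f"clutch_{k}": v for k, v in pair_summary.items()})
    if len(nests_a):
        nests_a = nests_a.dropna(subset=["first_egg_date"]).copy()
        nests_a["fed_doy"] = pd.to_datetime(
            nests_a["first_egg_date"]).dt.dayofyear.astype(float)
        nests_a["outcome_bin"] = (nests_a["outcome"] == "success").astype(int)
        nests_a["prop_fledged"] = nests_a["n_fledglings"] / nests_a["clutch_size"]
        nests_a["prop_fledged"] = nests_a["prop_fledged"].clip(0, 1)
        nests_a, n_dropped = apply_exclusions(nests_a, config.excluded_years)
        funnel["nests_used"] = len(nests_a)
        funnel["nests_excluded_by_year"] = n_dropped

    # --- 5. model selection ----------------------------------------------
    specs: dict[str, tuple[sel.ModelSpec, pd.DataFrame]] = {
        "year_round_condition": (sel.ModelSpec(
            "relative_condition", "gaussian",
            ("strategy", "area", "sex", "doy", "strategy:area"),
            group="bird_id", scale_terms=("doy",)), cond_rows),
        "pre_incubation_condition": (sel.ModelSpec(
            "relative_condition", "gaussian",
            ("strategy", "area", "sex", "doy", "strategy:area"),
            group="bird_id", scale_terms=("doy",)), pre_rows),
        "first_egg_date": (sel.ModelSpec(
            "fed_doy", "gaussian", ("strategy", "area"),
            scale_terms=("fed_doy",)), nests_a),
        "clutch_size": (sel.ModelSpec(
            "clutch_size", "cmp-log", ("strategy", "area", "fed_doy"),
            scale_terms=("fed_doy",)), nests_a),
        "n_fledglings": (sel.ModelSpec(
            "n_fledglings", "poisson-log", ("strategy", "area", "fed_doy"),
            scale_terms=("fed_doy",)), nests_a),
        "nest_outcome": (sel.ModelSpec(
            "outcome_bin", "binomial-logit", ("strategy", "area", "fed_doy"),
            scale_terms=("fed_doy",)), nests_a),
        "fledging_probability": (sel.ModelSpec(
            "prop_fledged", "quasibinomial-logit", ("strategy", "area", "fed_doy"),
            weights="clutch_size", scale_terms=("fed_doy",)), nests_a),
        "chick_condition": (sel.ModelSpec(
            "brood_condition", "gaussian", ("strategy", "area")),
            nests_a.dropna(subset=["brood_condition"]) if len(nests_a) else nests_a),
    }
    selection: dict[str, sel.SelectionTable] = {}
    for name, (spec, data) in specs.items():
        if data is None or len(data) < 15:
            log.append(f"analysis {name} skipped (n={0 if data is None else len(data)})")
            continue
        try:
            selection[name] = sel.rank_subsets(spec, data)
        except Exception as exc:
            log.append(f"analysis {name} failed: {exc}")
    posthoc = None
    tab = selection.get("pre_incubation_condition")
    if tab is not None and "strategy:area" in tab.final.spec.terms:
        posthoc = sel.posthoc_contrasts(tab.final, pre_rows)
    return AnalysisReport(strategy_counts, consistency, funnel, provenance_counts,
                          wing_info, condition_fit, selection, posthoc, log)


def run_sensitivity(config: AnalysisConfig) -> dict:
    """Re-run the full analysis per isotope cutoff and compare final models.

    Returns per-cutoff migrant counts and final-model term sets, plus a
    concordance flag (True when all cutoffs select identical final models
    for every analysis that ran under all cutoffs).
    """
    tables, _ = _load_tables(config)
    by_cutoff = strat.sensitivity_analysis(
        tables["resightings"], tables["geolocator_fixes"],
        tables["feather_isotopes"], config.rules, config.breeding_areas)
    finals: dict[float, dict[str, str]] = {}
    migrants = strat.migrant_counts(by_cutoff)
    for cutoff, calls in by_cutoff.items():
        report = run_pipeline(config, tables=tables, calls=calls)
        finals[cutoff] = report.final_terms()
    common = set.intersection(*[set(f) for f in finals.values()])
    concordant = all(
        len({finals[c][name] for c in finals}) == 1 for name in common
    )
    return {"migrant_counts": migrants, "final_terms": finals,
            "analyses_compared": sorted(common), "concordant": concordant}
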