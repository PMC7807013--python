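"""Synthetic cohort generator: construction properties and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from partmig.simulate import (ConditionParams, DetectionParams, IsotopeParams,
                              SimulationConfig, generate_cohort,
                              generate_condition_series)


class TestValidation:
    @pytest.mark.parametrize("make,field", [
        (lambda: SimulationConfig(p_migrant=1.5), "p_migrant"),
        (lambda: SimulationConfig(p_switch=-0.1), "p_switch"),
        (lambda: SimulationConfig(years=()), "years"),
        (lambda: SimulationConfig(n_individuals=0), "n_individuals"),
        (lambda: SimulationConfig(area_assignment={"A-rich": 0.8, "B-poor": 0.1}),
         "area_assignment"),
        (lambda: IsotopeParams(sd=0.0), "isotope_params.sd"),
        (lambda: DetectionParams(p_capture=2.0), "detection_params.p_capture"),
        (lambda: ConditionParams(residual_sd=-1.0), "condition_params.residual_sd"),
    ])
    def test_invalid_config_names_field(self, make, field):
        with pytest.raises(ValueError, match=field.replace(".", r"\.")):
            make()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        t1, _ = generate_cohort(SimulationConfig(seed=5, n_individuals=30))
        t2, _ = generate_cohort(SimulationConfig(seed=5, n_individuals=30))
        for name in t1:
            assert t1[name].to_csv(index=False) == t2[name].to_csv(index=False)

    def test_different_seed_differs(self):
        t1, _ = generate_cohort(SimulationConfig(seed=5, n_individuals=30))
        t2, _ = generate_cohort(SimulationConfig(seed=6, n_individuals=30))
        assert not t1["captures"].equals(t2["captures"])


class TestStrategyTruth:
    def test_all_resident_when_p_migrant_zero(self):
        tables, truth = generate_cohort(SimulationConfig(
            seed=2, n_individuals=40, p_migrant=0.0, p_switch=0.0))
        assert (truth.bird_years["strategy"] == "resident").all()
        lat = tables["geolocator_fixes"]["latitude"]
        assert (lat >= 36.0).all()

    def test_marginal_migrant_frequency(self):
        """First-year strategy frequency within binomial 99% bounds of
        p_migrant at n=500 individuals."""
        cfg = SimulationConfig(seed=3, n_individuals=500, years=(2015,))
        _, truth = generate_cohort(cfg)
        frac = (truth.bird_years["strategy"] == "migrant").mean()
        half = 2.576 * np.sqrt(0.45 * 0.55 / 500)
        assert abs(frac - 0.45) < half

    def test_winter_fix_latitudes_respect_truth(self, default_cohort):
        tables, truth = default_cohort
        strategy = {(r.bird_id, r.year): r.strategy
                    for r in truth.bird_years.itertuples()}
        fx = tables["geolocator_fixes"].copy()
        dt = pd.to_datetime(fx["datetime"])
        fx["year"] = np.where(dt.dt.month >= 7, dt.dt.year + 1, dt.dt.year)
        in_win = (((dt.dt.month == 11) | (dt.dt.month == 12))
                  | ((dt.dt.month == 1) & (dt.dt.day <= 15)))
        win = fx[in_win]
        for (bird, year), grp in win.groupby(["bird_id", "year"]):
            s = strategy[(bird, year)]
            if s == "resident":
                assert (grp["latitude"] >= 36.0).all()
            else:
                assert (grp["latitude"] < 23.0).sum() >= 2

    def test_residents_never_resighted_outside_breeding_areas(self, default_cohort):
        tables, truth = default_cohort
        strategy = {(r.bird_id, r.year): r.strategy
                    for r in truth.bird_years.itertuples()}
        rs = tables["resightings"]
        for r in rs.itertuples():
            d = pd.Timestamp(r.date)
            year = d.year + 1 if d.month >= 11 else d.year
            if r.area in ("A-rich", "B-poor"):
                assert strategy[(r.bird_id, year)] == "resident"
            else:
                assert strategy[(r.bird_id, year)] == "migrant"


class TestIsotopes:
    def test_migrant_tail_fraction_matches_normal_oracle(self):
        """With p_premoult=0, the fraction of migrant feathers above -20
        converges to the normal tail probability 1 - Phi((-20+16.5)/1.2)."""
        cfg = SimulationConfig(
            seed=7, n_individuals=600, years=(2015, 2016), p_migrant=1.0,
            p_switch=0.0,
            isotope_params=IsotopeParams(-23.5, -16.5, 1.2, p_premoult=0.0),
            detection_params=DetectionParams(p_feather_sample=1.0))
        tables, _ = generate_cohort(cfg)
        iso = tables["feather_isotopes"]
        frac = (iso["d13c"] > -20.0).mean()
        expected = 1 - norm.cdf((-20.0 + 16.5) / 1.2)   # ~0.9982
        assert frac == pytest.approx(expected, abs=0.006)

    def test_premoult_migrants_carry_resident_signature(self):
        cfg = SimulationConfig(
            seed=8, n_individuals=600, years=(2015,), p_migrant=1.0,
            isotope_params=IsotopeParams(p_premoult=0.5),
            detection_params=DetectionParams(p_feather_sample=1.0))
        tables, _ = generate_cohort(cfg)
        frac_low = (tables["feather_isotopes"]["d13c"] <= -20.0).mean()
        assert frac_low == pytest.approx(0.5, abs=0.06)


class TestConditionSeries:
    def _series(self, **cond_kw):
        base = dict(baseline=3.0, amplitude=0.05, sex_offset=0.0,
                    individual_sd=0.001, residual_sd=0.05, area_offset=0.0,
                    deficit={"A-rich": 0.0, "B-poor": 0.0})
        base.update(cond_kw)
        cfg = SimulationConfig(
            seed=11, n_individuals=400, years=(2015, 2016),
            condition_params=ConditionParams(**base),
            detection_params=DetectionParams(p_capture=0.2))
        tables, truth = generate_cohort(cfg)
        cap = tables["captures"]
        cap = cap.assign(cond=cap["mass"] / cap["p8"],
                         doy=pd.to_datetime(cap["date"]).dt.dayofyear)
        strategy = {(r.bird_id, r.year): r.strategy
                    for r in truth.bird_years.itertuples()}
        cap["strategy"] = [strategy[(b, y)] for b, y in zip(cap.bird_id, cap.year)]
        return cap

    def test_zero_deficit_means_equal(self):
        cap = self._series()
        pre = cap[cap["doy"] < 122]
        m = pre[pre.strategy == "migrant"]["cond"]
        r = pre[pre.strategy == "resident"]["cond"]
        se = np.sqrt(m.var() / len(m) + r.var() / len(r))
        assert abs(m.mean() - r.mean()) < 3 * se

    def test_sex_offset_by_construction(self):
        cap = self._series(sex_offset=0.1)
        diff = (cap[cap.sex == "male"]["cond"].mean()
                - cap[cap.sex == "female"]["cond"].mean())
        assert diff == pytest.approx(0.1, abs=0.02)

    def test_deficit_applies_only_pre_incubation(self):
        cap = self._series(deficit={"A-rich": 0.0, "B-poor": 0.3})
        b = cap[cap.area == "B-poor"]
        pre = b[b.doy < 122]
        post = b[b.doy >= 122]
        pre_diff = (pre[pre.strategy == "resident"].cond.mean()
                    - pre[pre.strategy == "migrant"].cond.mean())
        post_diff = (post[post.strategy == "resident"].cond.mean()
                     - post[post.strategy == "migrant"].cond.mean())
        assert pre_diff == pytest.approx(0.3, abs=0.05)
        assert abs(post_diff) < 0.05

    def test_degenerate_constant_condition(self):
        cap = self._series(amplitude=0.0, individual_sd=0.0, residual_sd=0.0)
        assert np.allclose(cap["cond"], 3.0, atol=1e-9)


def test_clutch_sizes_underdispersed_and_declining(default_cohort):
    tables, truth = default_cohort
    nests = truth.nests
    assert nests["true_clutch"].var() < nests["true_clutch"].mean()
    fed_doy = pd.to_datetime(nests["true_first_egg"]).dt.dayofyear
    r = np.corrcoef(fed_doy, nests["true_clutch"])[0, 1]
    assert r < -0.1


def test_truth_traceability(default_cohort):
    """Every observation row joins to exactly one truth row."""
    tables, truth = default_cohort
    by_key = truth.bird_years.set_index(["bird_id", "year"])
    assert by_key.index.is_unique
    for r in tables["captures"].itertuples():
        assert (r.bird_id, r.year) in by_key.index
    nest_keys = set(truth.nests["nest_id"])
    assert set(tables["nests"]["nest_id"]) == nest_keys
    assert set(tables["nest_chicks"]["nest_id"]) <= nest_keys
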