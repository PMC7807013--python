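"""Information criteria, Delta-2 selection and post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest

from partmig.selection import (FittedModel, ModelSpec, admissible_subsets,
                               aicc, apply_delta2_rule, estimate_chat,
                               fit_model, posthoc_contrasts, qaicc,
                               rank_subsets)


def _dummy(terms, k, criterion):
    spec = ModelSpec("y", "gaussian", terms)
    return FittedModel(spec, pd.Series(dtype=float), pd.Series(dtype=float),
                       0.0, 100, k, criterion, True)


class TestCriteria:
    def test_aicc_closed_form(self):
        # -2(-47) + 2*3 + 2*3*4/(20-4) = 94 + 6 + 1.5
        assert aicc(-47.0, 3, 20) == pytest.approx(101.5, abs=1e-12)

    def test_qaicc_with_unit_chat_is_aicc_with_extra_parameter(self):
        assert qaicc(-47.0, 1.0, 3, 20) == pytest.approx(aicc(-47.0, 4, 20), abs=1e-12)

    def test_aicc_approaches_aic_for_large_n(self):
        k, llf = 3, -47.0
        aic = -2 * llf + 2 * k
        assert abs(aicc(llf, k, 10 ** 7) - aic) < 1e-5

    def test_aicc_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestDelta2Rule:
    def test_fewest_parameters_within_delta2(self):
        models = [_dummy(("a", "b", "c", "d"), 4, 100.0),
                  _dummy(("a",), 2, 101.1),
                  _dummy((), 1, 103.0)]
        tab = apply_delta2_rule(models)
        assert tab.delta[0] == 0.0
        assert list(tab.delta2_mask) == [True, True, False]
        assert tab.final.k == 2 and tab.final.term_label == "a"

    def test_invariant_under_likelihood_shift(self):
        models = [_dummy(("a", "b"), 4, 100.0), _dummy(("a",), 2, 101.1),
                  _dummy((), 1, 103.0)]
        shifted = [_dummy(m.spec.terms, m.k, m.criterion + 57.3) for m in models]
        assert (apply_delta2_rule(models).final.term_label
                == apply_delta2_rule(shifted).final.term_label)

    def test_tie_breaks_to_better_criterion(self):
        models = [_dummy(("a",), 2, 100.0), _dummy(("b",), 2, 100.9)]
        assert apply_delta2_rule(models).final.term_label == "a"


def test_marginality_of_candidate_sets():
    subs = admissible_subsets(("strategy", "area", "sex", "strategy:area"))
    for combo in subs:
        if "strategy:area" in combo:
            assert "strategy" in combo and "area" in combo
    # 8 main-effect subsets + 2 with the interaction (sex free)
    assert len(subs) == 10


def test_rank_subsets_selects_true_predictor():
    rng = np.random.default_rng(2)
    n = 200
    df = pd.DataFrame({
        "x1": rng.normal(size=n), "x2": rng.normal(size=n),
    })
    df["y"] = 2.0 * df["x1"] + rng.normal(size=n)
    tab = rank_subsets(ModelSpec("y", "gaussian", ("x1", "x2")), df)
    assert "x1" in tab.final.spec.terms
    assert "x2" not in tab.final.spec.terms


def test_null_true_selection_mostly_picks_null():
    """With all effects zero, the fewest-parameter rule keeps the null model
    in the clear majority of replicates."""
    rng = np.random.default_rng(42)
    wins = 0
    reps = 200
    for _ in range(reps):
        n = 100
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = rng.normal(size=n)
        tab = rank_subsets(ModelSpec("y", "gaussian", ("x1", "x2")), df)
        if tab.final.spec.terms == ():
            wins += 1
    assert wins > reps / 2


class TestChat:
    def _binom_fit(self, rho=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        trials = rng.integers(3, 8, size=n)
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 0.4 * x)))
        if rho > 0:  # beta-binomial overdispersion
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            p = rng.beta(a, b)
        succ = rng.binomial(trials, p)
        df = pd.DataFrame({"prop": succ / trials, "w": trials, "x": x})
        spec = ModelSpec("prop", "quasibinomial-logit", ("x",), weights="w")
        return fit_model(spec, df, chat=1.0)

    def test_chat_near_one_for_binomial_data(self):
        fit = self._binom_fit()
        assert 0.8 <= estimate_chat(fit.result) <= 1.2

    def test_chat_detects_betabinomial_overdispersion(self):
        hits = sum(estimate_chat(self._binom_fit(rho=0.1, seed=s).result) > 1
                   for s in range(20))
        assert hits >= 19

    def test_chat_saturated_model_errors(self):
        rng = np.random.default_rng(0)
        import statsmodels.api as sm
        y = rng.integers(0, 2, size=3).astype(float)
        X = np.eye(3)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        with pytest.raises(ValueError):
            estimate_chat(res)


class TestPosthoc:
    def _sim(self, effect_b, seed, n=141):
        rng = np.random.default_rng(seed)
        birds = [f"b{i}" for i in rng.integers(0, 100, size=n)]
        strategy = rng.choice(["migrant", "resident"], size=n)
        area = rng.choice(["A-rich", "B-poor"], size=n)
        b_int = {b: rng.normal(0, 0.5) for b in set(birds)}
        y = (effect_b * ((strategy == "migrant") & (area == "B-poor"))
             + np.array([b_int[b] for b in birds]) + rng.normal(size=n))
        return pd.DataFrame({"y": y, "strategy": strategy, "area": area,
                             "bird_id": birds})

    def _fit_interaction(self, df):
        spec = ModelSpec("y", "gaussian",
                         ("strategy", "area", "strategy:area"), group="bird_id")
        return fit_model(spec, df)

    def test_adjusted_p_at_least_raw_p(self):
        df = self._sim(-1.0, 1)
        ph = posthoc_contrasts(self._fit_interaction(df), df)
        assert np.all(ph.p_adjusted >= ph.p_unadjusted - 1e-12)
        assert np.all((ph.p_adjusted >= 0) & (ph.p_adjusted <= 1))

    def test_refuses_without_interaction(self):
        df = self._sim(0.0, 2)
        fm = fit_model(ModelSpec("y", "gaussian", ("strategy", "area"),
                                 group="bird_id"), df)
        with pytest.raises(ValueError):
            posthoc_contrasts(fm, df)

    def test_deficit_area_has_smaller_p(self):
        """A deficit only in the poor area shows up in that area's contrast."""
        hits = 0
        reps = 15
        for s in range(reps):
            df = self._sim(-1.0, 100 + s)
            ph = posthoc_contrasts(self._fit_interaction(df), df)
            lbl = dict(zip(ph.labels, ph.p_adjusted))
            pa = [v for k, v in lbl.items() if "A-rich" in k and "|" in k and "mean" not in k][0]
            pb = [v for k, v in lbl.items() if "B-poor" in k and "|" in k and "mean" not in k][0]
            hits += pb < pa
        assert hits >= 0.9 * reps

    def test_null_type_one_error_conservative(self):
        rejections = 0
        reps = 60
        for s in range(reps):
            df = self._sim(0.0, 500 + s)
            ph = posthoc_contrasts(self._fit_interaction(df), df)
            rejections += int(np.any(ph.p_adjusted[:2] < 0.05))
        # family-wise error across the two within-area contrasts stays near
        # or below nominal (binomial slack on 60 reps)
        assert rejections <= np.ceil(0.05 * reps + 2.5 * np.sqrt(0.05 * 0.95 * reps))


def test_mixed_model_interaction_recovery():
    """Gaussian mixed model recovers an area-specific deficit's sign and
    size within 2 SE at the study's sample size."""
    rng = np.random.default_rng(9)
    n = 141
    birds = [f"b{i}" for i in rng.integers(0, 90, size=n)]
    strategy = rng.choice(["migrant", "resident"], size=n)
    area = rng.choice(["A-rich", "B-poor"], size=n)
    b_int = {b: rng.normal(0, 0.5) for b in set(birds)}
    deficit = -1.0
    y = (deficit * ((strategy == "migrant") & (area == "B-poor"))
         + np.array([b_int[b] for b in birds]) + rng.normal(size=n))
    df = pd.DataFrame({"y": y, "strategy": strategy, "area": area, "bird_id": birds})
    fm = fit_model(ModelSpec("y", "gaussian", ("strategy", "area", "strategy:area"),
                             group="bird_id"), df)
    name = [i for i in fm.params.index if ":" in i][0]
    # interaction coded vs (migrant, A-rich) baseline: resident-in-B effect +1
    assert fm.params[name] == pytest.approx(-deficit, abs=2 * fm.bse[name])
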