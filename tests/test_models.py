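"""Regression fitters against closed forms and small independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import cnvburden as cb
from cnvburden.errors import ConfigError, SeparationError
from cnvburden.models import ModelSpec, score_insomnia

from conftest import phenotypes_for, profiles_from_carriers


class TestScoreInsomnia:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("yes", "yes", 2),
            ("no", "no", 0),
            ("yes", "no", 1),
            ("no", "yes", 1),
            ("yes", "missing", None),
            (None, "yes", None),
            (float("nan"), "no", None),
        ],
    )
    def test_item_scoring(self, a, b, expected):
        assert score_insomnia(a, b) == expected


class TestCaseControl:
    def test_single_binary_predictor_equals_2x2_log_odds_ratio(self):
        # 50/1000 cases exposed vs 10/1000 controls
        carrier = [True] * 50 + [False] * 950 + [True] * 10 + [False] * 990
        y = [1] * 1000 + [0] * 1000
        prof = profiles_from_carriers(carrier)
        ph = phenotypes_for(2000, case_status=y)
        est = {e.term: e for e in cb.fit_case_control(prof, ph, ModelSpec(model_id=1))}
        expected = math.log((50 * 990) / (10 * 950))
        assert est["DEL_target"].beta == pytest.approx(expected, abs=1e-6)
        assert est["DEL_target"].or_value == pytest.approx(math.exp(expected), rel=1e-6)

    def test_all_zero_burden_gives_intercept_only_fit(self):
        prof = profiles_from_carriers([False] * 100)
        ph = phenotypes_for(100, case_status=[1] * 30 + [0] * 70)
        with pytest.warns(UserWarning):
            ests = cb.fit_case_control(prof, ph, ModelSpec(model_id=1))
        assert [e.term for e in ests] == ["intercept"]
        assert ests[0].beta == pytest.approx(math.log(0.3 / 0.7), abs=1e-9)

    def test_flat_logistic_equals_2x2_log_or_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(5, 200, size=4)
            carrier = [True] * a + [False] * b + [True] * c + [False] * d
            y = [1] * (a + b) + [0] * (c + d)
            prof = profiles_from_carriers(carrier)
            ph = phenotypes_for(len(y), case_status=y)
            est = {e.term: e.beta for e in cb.fit_case_control(prof, ph, ModelSpec(model_id=1))}
            assert est["DEL_target"] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)

    def test_complete_separation_flagged_and_map_recovers(self):
        carrier = [True] * 20 + [False] * 80 + [False] * 100
        y = [1] * 100 + [0] * 100
        prof = profiles_from_carriers(carrier)
        ph = phenotypes_for(200, case_status=y)
        with pytest.raises(SeparationError):
            cb.fit_case_control(prof, ph, ModelSpec(model_id=1))
        ests = cb.fit_case_control(
            prof, ph, ModelSpec(model_id=1, prior_mode="weakly_informative")
        )
        beta = {e.term: e.beta for e in ests}["DEL_target"]
        assert np.isfinite(beta) and 0 < beta < 10

    def test_map_close_to_ml_when_well_conditioned(self):
        carrier = [True] * 120 + [False] * 880 + [True] * 60 + [False] * 940
        y = [1] * 1000 + [0] * 1000
        prof = profiles_from_carriers(carrier)
        ph = phenotypes_for(2000, case_status=y)
        flat = {e.term: e.beta for e in cb.fit_case_control(prof, ph, ModelSpec(model_id=1))}
        wi = {e.term: e.beta for e in cb.fit_case_control(
            prof, ph, ModelSpec(model_id=1, prior_mode="weakly_informative"))}
        assert wi["DEL_target"] == pytest.approx(flat["DEL_target"], abs=0.05)

    def test_orthogonal_balanced_covariate_leaves_burden_estimate_unchanged(self):
        # 2x2 balanced design; case fraction depends only on the burden cell,
        # so the covariate's MLE is exactly zero and the score equations split
        rows = []
        for x in (0, 1):
            for z in (-1.0, 1.0):
                p = 0.3 if x == 0 else 0.6
                n_cell = 200
                n_case = int(round(p * n_cell))
                rows += [(x, z, 1)] * n_case + [(x, z, 0)] * (n_cell - n_case)
        df = pd.DataFrame(rows, columns=["x", "z", "y"])
        prof = profiles_from_carriers(df["x"].astype(bool).tolist())
        ph = phenotypes_for(len(df), case_status=df["y"].tolist(), z=df["z"].tolist())
        plain = {e.term: e.beta for e in cb.fit_case_control(prof, ph, ModelSpec(model_id=1))}
        adjusted = {e.term: e.beta for e in cb.fit_case_control(
            prof, ph, ModelSpec(model_id=1, covariates=("z",)))}
        assert adjusted["DEL_target"] == pytest.approx(plain["DEL_target"], abs=1e-6)
        assert abs(adjusted["z"]) < 1e-6

    def test_singleton_families_match_independent_fit(self):
        carrier = [True] * 40 + [False] * 160 + [True] * 20 + [False] * 180
        y = [1] * 200 + [0] * 200
        prof = profiles_from_carriers(carrier)
        fam = [f"F{i}" for i in range(400)]
        ph = phenotypes_for(400, case_status=y, family_id=fam)
        indep = {e.term: e.beta for e in cb.fit_case_control(prof, ph, ModelSpec(model_id=1))}
        for method in ("robust", "gee_exchangeable"):
            clustered = {
                e.term: e.beta
                for e in cb.fit_case_control(
                    prof, ph,
                    ModelSpec(model_id=1, cluster_by="family_id", cluster_method=method),
                )
            }
            assert clustered["DEL_target"] == pytest.approx(indep["DEL_target"], abs=1e-5)

    def test_random_intercept_mode_runs(self, genome):
        cfg = cb.SimulationConfig(n_cases=150, n_controls=150, family_size=2,
                                  family_rate_sd=0.4, cnv_rate=1.0, seed=17)
        calls, ph = cb.simulate_cohort(genome, cfg)
        ann = cb.annotate_cnvs(calls, genome.genes)
        prof = cb.build_profiles(ann, ph["sample_id"].tolist())
        ests = cb.fit_case_control(
            prof, ph,
            ModelSpec(model_id=1, cluster_by="family_id", cluster_method="random_intercept"),
        )
        assert all(np.isfinite(e.beta) for e in ests)


class TestSleepDuration:
    def test_constant_outcome_gives_zero_slopes(self):
        prof = profiles_from_carriers([True] * 10 + [False] * 10, "DUP_target_n_genes")
        ph = phenotypes_for(20, sleep_duration_min=[600.0] * 20)
        est = {e.term: e.beta for e in cb.fit_sleep_duration(
            prof, ph, ModelSpec(model_id=3, outcome="sleep_duration_min"))}
        assert est["DUP_target"] == pytest.approx(0.0, abs=1e-9)
        assert est["intercept"] == pytest.approx(600.0)

    def test_five_point_toy_matches_hand_least_squares(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        yv = np.array([650.0, 640.0, 610.0, 615.0, 580.0])
        prof = profiles_from_carriers([False] * 5, "DUP_target_n_genes")
        prof["DUP_target_n_genes"] = x
        ph = phenotypes_for(5, sleep_duration_min=yv)
        est = {e.term: e.beta for e in cb.fit_sleep_duration(
            prof, ph, ModelSpec(model_id=3, outcome="sleep_duration_min"))}
        # normal equations by hand
        slope = ((x - x.mean()) * (yv - yv.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert est["DUP_target"] == pytest.approx(slope, abs=1e-9)
        assert est["intercept"] == pytest.approx(yv.mean() - slope * x.mean(), abs=1e-9)

    def test_z_scored_outcome_mode(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0, 0.0, 2.0, 4.0]
        yv = [660, 640, 615, 600, 580, 655, 620, 585.0]
        prof = profiles_from_carriers([False] * 8, "DUP_target_n_genes")
        prof["DUP_target_n_genes"] = x
        ph = phenotypes_for(8, sleep_duration_min=yv)
        raw = {e.term: e.beta for e in cb.fit_sleep_duration(
            prof, ph, ModelSpec(model_id=3, outcome="sleep_duration_min"))}
        z = {e.term: e.beta for e in cb.fit_sleep_duration(
            prof, ph, ModelSpec(model_id=3, outcome="sleep_duration_min", outcome_scale="z"))}
        sd = np.std(yv, ddof=0)
        assert z["DUP_target"] == pytest.approx(raw["DUP_target"] / sd, abs=1e-9)

    def test_underdetermined_fit_rejected(self):
        prof = profiles_from_carriers([True, False], "DUP_target_n_genes")
        ph = phenotypes_for(2, sleep_duration_min=[600.0, 610.0])
        with pytest.raises(ConfigError):
            cb.fit_sleep_duration(prof, ph, ModelSpec(model_id=3, outcome="sleep_duration_min"))


class TestInsomnia:
    def test_intercept_only_thresholds_are_cumulative_logits(self):
        counts = [0] * 600 + [1] * 300 + [2] * 100
        prof = profiles_from_carriers([False] * 1000)
        with pytest.warns(UserWarning):
            ests = cb.fit_insomnia(
                prof,
                phenotypes_for(1000, insomnia_traits=counts),
                ModelSpec(model_id=4, outcome="insomnia_traits"),
            )
        taus = {e.term: e.beta for e in ests}
        assert taus["threshold_1"] == pytest.approx(math.log(0.6 / 0.4), abs=1e-9)
        assert taus["threshold_2"] == pytest.approx(math.log(0.9 / 0.1), abs=1e-9)

    def test_slope_and_threshold_recovery_on_generated_ordinal_data(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.poisson(0.8, size=n).astype(float)
        tau1, tau2, beta = 0.5, 2.2, 0.6
        u = rng.random(n)
        from scipy.special import expit

        yv = (u < expit(beta * x - tau1)).astype(int) + (u < expit(beta * x - tau2))
        prof = profiles_from_carriers([False] * n, "DUP_target_n_genes")
        prof["DUP_target_n_genes"] = x
        ests = {e.term: e for e in cb.fit_insomnia(
            prof,
            phenotypes_for(n, insomnia_traits=yv),
            ModelSpec(model_id=4, outcome="insomnia_traits"),
        )}
        assert ests["DUP_target"].beta == pytest.approx(beta, abs=3 * ests["DUP_target"].se)
        assert ests["threshold_1"].beta == pytest.approx(tau1, abs=0.2)
        assert ests["threshold_2"].beta == pytest.approx(tau2, abs=0.25)

    def test_missing_scores_excluded_and_levels_validated(self):
        prof = profiles_from_carriers([False] * 6)
        ph = phenotypes_for(6, insomnia_traits=pd.array([0, 1, 2, None, 1, 0], dtype="Int64"))
        with pytest.warns(UserWarning):
            ests = cb.fit_insomnia(prof, ph, ModelSpec(model_id=4, outcome="insomnia_traits"))
        assert len(ests) == 2  # two thresholds from the 5 scored individuals

    def test_cumulative_probabilities_monotone_and_sum_to_one(self):
        from scipy.special import expit

        taus = [0.45, 2.2]
        for eta in (-2.0, 0.0, 1.5):
            p_ge = [expit(eta - t) for t in taus]
            probs = [1 - p_ge[0], p_ge[0] - p_ge[1], p_ge[1]]
            assert p_ge[0] >= p_ge[1]
            assert sum(probs) == pytest.approx(1.0)
            assert all(p >= 0 for p in probs)


class TestBonferroni:
    def test_gate_thresholds(self):
        mk = lambda p: cb.EffectEstimate("t", 0.0, 1.0, -2.0, 2.0, p)  # noqa: E731
        gated = cb.bonferroni_gate([mk(0.02), mk(0.001), mk(0.016)])
        assert [e.significant for e in gated] == [False, True, True]
        assert cb.bonferroni_gate([mk(0.03)], n_tests=1)[0].significant is True
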