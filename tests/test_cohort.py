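"""Synthetic cohort generator: sizes, timing, toxicity and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import rtmicrocost as rtm
from rtmicrocost.cohort import GenerationError, sample_session_duration, sample_toxicity
from rtmicrocost.config import ConfigError, TimingModel, ToxicityEndpointModel


class TestCohortStructure:
    def test_exact_arm_sizes(self, study_cohort):
        _, patients, _, _ = study_cohort
        counts = patients["arm"].value_counts()
        assert counts["VMAT"] == 106 and counts["HT"] == 49
        assert len(patients) == 155

    def test_session_counts_match_plan(self, study_cohort):
        """SIB plans deliver exactly 34 fractions, sequential exactly 40."""
        _, patients, events, _ = study_cohort
        sessions = (
            events[events["phase"] == "session"].groupby("patient_id").size()
        )
        merged = patients.set_index("patient_id").join(sessions.rename("n_sessions"))
        assert (merged["n_sessions"] == merged["fractions"]).all()
        assert set(merged["fractions"]) == {34, 40}
        # session indices run 1..fractions without gaps
        idx_max = (
            events[events["phase"] == "session"]
            .groupby("patient_id")["session_index"]
            .max()
        )
        assert (idx_max == merged["fractions"]).all()

    def test_all_minutes_positive_finite(self, study_cohort):
        _, _, events, _ = study_cohort
        assert np.isfinite(events["personnel_minutes"]).all()
        assert np.isfinite(events["equipment_minutes"]).all()
        assert (events["personnel_minutes"] >= 0).all()
        assert (events[events["phase"] == "session"]["equipment_minutes"] > 0).all()

    def test_every_patient_logs_every_phase(self, study_cohort):
        _, patients, events, _ = study_cohort
        phases_per_patient = events.groupby("patient_id")["phase"].nunique()
        assert (phases_per_patient.reindex(patients["patient_id"]) == 5).all()

    def test_psa_cap_respected(self):
        config = rtm.default_cohort_config(n_vmat=300, n_ht=150, seed=3)
        config.covariates.psa_cap = 40.0
        patients = rtm.generate_patients(config)
        assert patients["psa"].max() <= 40.0
        assert (patients["psa"] == 40.0).any()  # the cap binds in the tail

    def test_seed_reproducibility(self):
        config = rtm.default_cohort_config(n_vmat=30, n_ht=15, seed=99)
        first = rtm.generate_cohort(config)
        second = rtm.generate_cohort(config)
        for a, b in zip(first, second):
            pd.testing.assert_frame_equal(a, b)
        third = rtm.generate_cohort(rtm.default_cohort_config(30, 15, seed=100))
        assert not third[0]["age"].equals(first[0]["age"])

    def test_config_yaml_round_trip(self, tmp_path):
        config = rtm.default_cohort_config(n_vmat=25, n_ht=12, seed=5)
        path = tmp_path / "cohort.yaml"
        config.to_yaml(path)
        loaded = rtm.CohortConfig.from_yaml(path)
        a, b = rtm.generate_cohort(config), rtm.generate_cohort(loaded)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_infeasible_arm_raises(self):
        config = rtm.default_cohort_config(n_vmat=5, n_ht=5, seed=1)
        config.assignment.intercept = -40.0  # HT essentially unreachable
        with pytest.raises(GenerationError, match="HT"):
            rtm.generate_patients(config)

    def test_invalid_config_rejected(self):
        config = rtm.default_cohort_config()
        config.n_ht = 0
        with pytest.raises(ConfigError):
            config.validate()
        config = rtm.default_cohort_config()
        config.covariates.ct_probs = (0.5, 0.5, 0.2, 0.0)
        with pytest.raises(ConfigError, match="sum to 1"):
            config.validate()


class TestSessionDurations:
    @pytest.mark.parametrize(
        "arm,session_index,expected_median",
        [
            ("VMAT", 1, 20.0),
            ("VMAT", 2, 15.0),
            ("VMAT", 9, 13.0),
            ("HT", 1, 18.0),
            ("HT", 3, 18.0),
            ("HT", 9, 17.0),
        ],
    )
    def test_stratum_medians(self, arm, session_index, expected_median, rng):
        draws = sample_session_duration(arm, session_index, rng, size=10_000)
        assert np.median(draws) == pytest.approx(expected_median, rel=0.02)
        assert (draws > 0).all()

    def test_zero_noise_is_degenerate(self, rng):
        timing = TimingModel(session_sigma=0.0)
        draws = sample_session_duration("VMAT", 5, rng, timing=timing, size=100)
        assert np.all(draws == 13.0)

    def test_invalid_session_index(self, rng):
        with pytest.raises(ConfigError):
            sample_session_duration("VMAT", 0, rng)


class TestToxicitySampling:
    def test_category_probabilities_inverse_logit(self):
        """Cell probabilities are successive differences of expit(cutpoints)."""
        probs = rtm.category_probabilities((-2.19, -0.04, 3.18))
        # frozen from direct inverse-logit arithmetic
        assert probs == pytest.approx((0.10065, 0.38935, 0.47007, 0.03993), abs=1e-5)
        assert probs.sum() == pytest.approx(1.0)
        shifted = rtm.category_probabilities((-2.19, -0.04, 3.18), log_or=0.6)
        assert shifted[0] < probs[0]  # positive shift pushes mass to worse grades
        assert shifted[3] > probs[3]

    def test_non_monotone_cutpoints_rejected(self, rng):
        model = ToxicityEndpointModel(cutpoints=(0.5, 0.1, 2.0))
        with pytest.raises(ConfigError, match="increasing"):
            sample_toxicity("HT", "GI", "acute", model, rng)

    def test_null_effect_equal_distributions(self, rng):
        model = ToxicityEndpointModel(cutpoints=(-1.0, 0.3, 2.5), log_or_vmat=0.0)
        expected = rtm.category_probabilities(model.cutpoints)
        for arm in ("VMAT", "HT"):
            grades, _ = sample_toxicity(arm, "GI", "acute", model, rng, size=20_000)
            observed = np.bincount(grades, minlength=4) / 20_000
            assert observed == pytest.approx(expected, abs=0.015)

    def test_positive_effect_orders_arms(self, rng):
        """A positive VMAT log-OR raises P(grade >= 2) for VMAT above HT."""
        model = ToxicityEndpointModel(cutpoints=(-1.0, 0.3, 2.5), log_or_vmat=0.8)
        p_ge2 = {}
        for arm in ("VMAT", "HT"):
            grades, _ = sample_toxicity(arm, "GU", "acute", model, rng, size=20_000)
            p_ge2[arm] = (grades >= 2).mean()
        # closed-form: P(>=2) = 1 - expit(c_2 - shift)
        assert p_ge2["HT"] == pytest.approx(1 - expit(0.3), abs=0.015)
        assert p_ge2["VMAT"] == pytest.approx(1 - expit(0.3 - 0.8), abs=0.015)
        assert p_ge2["VMAT"] > p_ge2["HT"]

    def test_onset_months_respect_windows(self, study_cohort):
        _, _, _, toxicity = study_cohort
        acute = toxicity[toxicity["window"] == "acute"]
        late = toxicity[toxicity["window"] == "late"]
        assert ((acute["months"] > 0) & (acute["months"] <= 3)).all()
        assert ((late["months"] >= 6) & (late["months"] <= 24)).all()


class TestConfounding:
    def test_null_assignment_balances_covariates(self):
        """Intercept-only assignment leaves both arms with the same covariates."""
        config = rtm.default_cohort_config(n_vmat=13677, n_ht=6323, seed=21)
        config.assignment = rtm.config.AssignmentModel(
            intercept=-0.8, age=0, performance=0, ct2=0, ct3=0, ct4=0, cn1=0, psa=0
        )
        patients = rtm.generate_patients(config)
        bal = rtm.balance_table(patients)
        assert (bal["unweighted_d"].abs() < 0.05).all()

    def test_cn_confounding_matches_assignment_model(self, large_patients):
        """Empirical per-arm cN1 rates match the assignment model's marginals.

        Oracle: P(cN1 | arm) computed from the generating model itself by
        integrating expit(linear predictor) over the covariate distribution
        (large Monte Carlo integration, independent of the cohort-assembly
        machinery).
        """
        config = rtm.default_cohort_config()
        cov, assign = config.covariates, config.assignment
        r = np.random.default_rng(2024)
        m = 400_000
        age = r.normal(cov.age_mean, cov.age_sd, m)
        perf = (r.random(m) < cov.p_performance_1_2).astype(int)
        ct = r.choice(4, size=m, p=np.asarray(cov.ct_probs))
        cn1 = (r.random(m) < cov.p_cn1).astype(int)
        psa = np.minimum(
            np.exp(r.normal(cov.psa_log_mean, cov.psa_log_sd, m)), cov.psa_cap
        )
        ps = expit(assign.linear_predictor(age, perf, ct, cn1, psa))
        p_cn1_ht = np.sum(ps * cn1) / np.sum(ps)
        p_cn1_vmat = np.sum((1 - ps) * cn1) / np.sum(1 - ps)
        assert p_cn1_ht > p_cn1_vmat  # the confounding direction

        empirical = large_patients.groupby("arm")["c_n_stage"].apply(
            lambda s: (s == "cN1").mean()
        )
        assert empirical["HT"] == pytest.approx(p_cn1_ht, abs=0.02)
        assert empirical["VMAT"] == pytest.approx(p_cn1_vmat, abs=0.02)
        assert empirical["HT"] > empirical["VMAT"]
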