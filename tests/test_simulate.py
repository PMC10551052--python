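"""Generative fidelity of the synthetic calibration-study machinery."""

import numpy as np
import pandas as pd
import pytest

from cloneirt import simulate as sim
from cloneirt.core import StructureCoefficients


def _zeroed_coefficients(mu_beta=0.3, mu_alpha=1.2):
    return StructureCoefficients(mu_beta=mu_beta, mu_alpha=mu_alpha,
                                 delta_beta=np.zeros(4), delta_alpha=np.zeros(4),
                                 rho=np.zeros(4))


class TestItemBank:
    def test_degenerate_structure_collapses(self):
        cfg = sim.desk_config(seed=1, coefficients=_zeroed_coefficients())
        rng = np.random.default_rng(0)
        bank, params, _ = sim.generate_item_bank(cfg, rng)
        assert np.allclose(params["beta"], 0.3)
        assert np.allclose(params["alpha"], 1.2)

    def test_difficulty_sd_matches_population_target(self):
        # large bank: the realized spread of difficulty approaches the target
        cfg = sim.SimulationConfig(n_templates=9984, n_sets=16,
                                   items_per_person=16, n_persons=10, seed=2)
        bank, params, _ = sim.generate_item_bank(cfg, np.random.default_rng(2))
        assert params["beta"].std() == pytest.approx(1.431, rel=0.03)

    def test_seed_determinism(self):
        cfg = sim.desk_config(seed=42)
        a = sim.generate_item_bank(cfg, np.random.default_rng(42))
        b = sim.generate_item_bank(cfg, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a[0].clones, b[0].clones)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_bank_layout(self):
        cfg = sim.desk_config(seed=3)
        bank, _, _ = sim.generate_item_bank(cfg, np.random.default_rng(3))
        assert len(bank) == 96
        for _, grp in bank.clones.groupby("template_id"):
            assert len(grp) == 6
            assert set(zip(grp["shape_set"], grp["distractor_type"])) == {
                (s, d) for s in (1, 2, 3) for d in ("MD", "PD")
            }
        # the RT attribute is orthogonalized against the other attributes
        q, r = bank.design_matrices()
        for col in (q[:, 0], q[:, 1], r[:, 0]):
            assert abs(np.corrcoef(r[:, 1], col)[0, 1]) < 1e-8


class TestPersons:
    def test_plain_normal_when_rho_zero(self):
        cfg = sim.desk_config(seed=4, n_persons=50_000,
                              coefficients=_zeroed_coefficients())
        persons = sim.generate_persons(cfg, np.random.default_rng(4))
        assert persons["theta"].mean() == pytest.approx(0.0, abs=0.02)
        assert persons["theta"].std() == pytest.approx(1.0, rel=0.02)

    def test_covariates_explain_the_implied_ability_variance(self):
        # with independent generative covariates the explained share is the
        # analytic value implied by the rho vector and the covariate
        # variances (gender's +/-0.5 coding has variance 1/4)
        cfg = sim.SimulationConfig(n_persons=100_000, seed=5)
        persons = sim.generate_persons(cfg, np.random.default_rng(5))
        x = persons[["age_z", "gender_code", "mean_rt_z", "delta_rt_z"]].to_numpy()
        y = persons["theta"].to_numpy()
        design = np.column_stack([np.ones(len(y)), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r2 = 1.0 - np.var(y - design @ coef) / np.var(y)
        rho = cfg.coefficients.rho
        var_x = np.array([1.0, 0.25, 1.0, 1.0])
        explained = float(np.sum(rho**2 * var_x))
        implied = explained / (explained + cfg.coefficients.residual_ability_variance)
        assert r2 == pytest.approx(implied, abs=0.01)

    def test_gender_balanced(self):
        cfg = sim.desk_config(seed=6, n_persons=300)
        persons = sim.generate_persons(cfg, np.random.default_rng(6))
        assert abs(persons["gender_code"].sum()) <= 0.5


class TestAssignment:
    def test_one_template_per_set_every_person(self):
        study = sim.simulate_study(sim.desk_config(seed=7, n_persons=40))
        for _, grp in study.assignment.groupby("person_id"):
            assert len(grp) == 16
            assert grp["template_id"].nunique() == 16
            assert sorted(grp["set_index"]) == list(range(16))

    def test_perfect_counterbalance_at_multiple_of_six(self):
        cfg = sim.desk_config(seed=8, n_persons=36)
        study = sim.simulate_study(cfg)
        counts = study.assignment.groupby("clone_id").size()
        # every template administered 36 times -> exactly 6 per clone
        assert (counts == 6).all()

    def test_administration_counts_at_full_scale(self):
        study = sim.simulate_study(sim.SimulationConfig(seed=9))
        per_template = study.assignment.groupby("template_id").size()
        per_clone = study.assignment.groupby("clone_id").size()
        assert per_template.mean() == pytest.approx(1501 * 16 / 64, rel=0.01)
        assert per_clone.mean() == pytest.approx(62.5, rel=0.01)
        assert per_clone.std() < 10


class TestResponses:
    def test_high_ability_accuracy_saturates(self):
        cfg = sim.desk_config(seed=10, n_persons=30)
        study = sim.simulate_study(cfg)
        persons = study.persons.assign(theta=8.0)
        rng = np.random.default_rng(1)
        resp, _ = sim.simulate_responses(study.assignment, study.item_params,
                                         persons, cfg.rt, rng)
        assert resp.loc[~resp["timeout"], "accuracy"].mean() > 0.97

    def test_missing_item_parameters_error(self):
        cfg = sim.desk_config(seed=10, n_persons=10)
        study = sim.simulate_study(cfg)
        params = study.item_params.iloc[:-5]
        with pytest.raises(ValueError, match="no item parameters"):
            sim.simulate_responses(study.assignment, params, study.persons,
                                   cfg.rt, np.random.default_rng(0))

    def test_rt_variance_decomposition_without_fixed_effects(self):
        # with all fixed-effect coefficients zero and no censoring the log-RT
        # variance is exactly person-intercept variance + residual variance
        rt_cfg = sim.RTConfig(accuracy=0, score=0, difficulty=0,
                              accuracy_score=0, accuracy_difficulty=0,
                              score_difficulty=0, accuracy_score_difficulty=0,
                              person_sd=0.3, residual_sd=0.4, censor_s=np.inf)
        cfg = sim.desk_config(seed=11, n_persons=2000, rt=rt_cfg)
        ss = np.random.SeedSequence(11)
        r1, r2, r3, r4 = (np.random.default_rng(s) for s in ss.spawn(4))
        bank, params, _ = sim.generate_item_bank(cfg, r1)
        persons = sim.generate_persons(cfg, r2)
        assign = sim.assign_items(bank, persons, cfg, r3)
        resp, _ = sim.simulate_responses(assign, params, persons, rt_cfg, r4,
                                         bank=None)   # no clone dwell offsets
        log_rt = np.log(resp["rt"])
        assert log_rt.var() == pytest.approx(0.3**2 + 0.4**2, rel=0.05)
        between = resp.assign(l=log_rt).groupby("person_id")["l"].mean().var()
        assert between == pytest.approx(0.3**2 + 0.4**2 / 16, rel=0.12)

    def test_censoring_and_timeout_coding(self):
        study = sim.simulate_study(sim.desk_config(seed=12, n_persons=400))
        r = study.responses
        assert ((r["rt"] > 0) & (r["rt"] <= 30.0)).all()
        assert (r.loc[r["timeout"], "accuracy"] == 0).all()
        assert (r.loc[r["timeout"], "rt"] == 30.0).all()

    def test_full_scale_mean_score(self):
        study = sim.simulate_study(sim.SimulationConfig(seed=13))
        scores = study.responses.groupby("person_id")["accuracy"].sum()
        assert scores.mean() == pytest.approx(9.6, abs=0.5)
        assert study.responses["timeout"].mean() < 0.04

    def test_injected_artifacts_meet_exclusion_definitions(self):
        # short-RT regime so no honest participant accumulates 4 timeouts
        rt_cfg = sim.RTConfig(intercept=np.log(10.0))
        cfg = sim.desk_config(seed=14, n_persons=300, rt=rt_cfg,
                              rapid_guess_rate=0.05, nonresponse_rate=0.03)
        study = sim.simulate_study(cfg)
        r = study.responses
        rapid_count = r.assign(rapid=(~r["timeout"]) & (r["rt"] < 3.0)) \
                       .groupby("person_id")["rapid"].sum()
        miss_count = r.groupby("person_id")["timeout"].sum()
        inj = study.injected.set_index("person_id")
        for pid in inj.index:
            if inj.loc[pid, "rapid_guesser"]:
                assert rapid_count[pid] >= 4
            if inj.loc[pid, "nonresponder"]:
                assert miss_count[pid] >= 4
        assert inj["rapid_guesser"].sum() == round(0.05 * 300)
        assert inj["nonresponder"].sum() == round(0.03 * 300)


class TestStudyDeterminism:
    def test_same_seed_identical_tables(self):
        a = sim.simulate_study(sim.desk_config(seed=99, n_persons=50))
        b = sim.simulate_study(sim.desk_config(seed=99, n_persons=50))
        pd.testing.assert_frame_equal(a.responses, b.responses)
        pd.testing.assert_frame_equal(a.persons, b.persons)

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="divisible"):
            sim.SimulationConfig(n_templates=60, n_sets=16)
        with pytest.raises(ValueError, match="one item per set"):
            sim.SimulationConfig(items_per_person=10)
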