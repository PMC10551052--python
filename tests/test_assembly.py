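"""Information curves, reliability, and mixed-integer form assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cloneirt import assembly as asm
from cloneirt import simulate as sim


def _toy_bank(seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for t in range(6):
        for dist in ("MD", "PD"):
            rows.append((cid, t, dist, rng.normal(0, 1), rng.uniform(0.8, 2.0)))
            cid += 1
    return pd.DataFrame(rows, columns=["clone_id", "template_id",
                                       "distractor_type", "beta", "alpha"])


class TestItemInformation:
    def test_two_parameter_maximum_closed_form(self):
        # with gamma=0 the information peaks at theta = beta/alpha at alpha^2/4
        beta, alpha = 0.7, 1.6
        grid = np.linspace(-4, 4, 4001)
        info = asm.item_information(grid, beta, alpha, gamma=0.0)
        assert grid[np.argmax(info)] == pytest.approx(beta / alpha, abs=0.01)
        assert info.max() == pytest.approx(alpha**2 / 4.0, rel=1e-4)

    def test_vanishes_in_the_tails(self):
        assert asm.item_information(-40.0, 0.0, 1.2) < 1e-10
        assert asm.item_information(40.0, 0.0, 1.2) < 1e-10

    def test_matches_finite_difference_fisher_information(self):
        # I = (dp/dtheta)^2 / (p (1-p)) for Bernoulli outcomes
        rng = np.random.default_rng(0)
        from cloneirt.core import response_probability
        for _ in range(20):
            th, b = rng.normal(size=2)
            a, g = rng.uniform(0.5, 2.5), rng.uniform(0, 0.3)
            h = 1e-6
            dp = (response_probability(th + h, b, a, g)
                  - response_probability(th - h, b, a, g)) / (2 * h)
            p = response_probability(th, b, a, g)
            oracle = dp**2 / (p * (1 - p))
            assert asm.item_information(th, b, a, g) == pytest.approx(oracle, abs=1e-6)


class TestTestCurves:
    def test_guessing_asymptote_quarter_of_maximum(self):
        params = pd.DataFrame({"beta": np.linspace(-1, 2, 12),
                               "alpha": np.full(12, 1.3),
                               "gamma": np.full(12, 0.25)})
        tcc, _ = asm.test_curves(params, [-50.0])
        assert tcc[0] == pytest.approx(3.0, abs=1e-9)

    def test_empty_set_zero_curves(self):
        tcc, tif = asm.test_curves(pd.DataFrame(columns=["beta", "alpha"]),
                                   [-1, 0, 1])
        assert np.allclose(tcc, 0.0) and np.allclose(tif, 0.0)

    def test_tcc_monotone_for_positive_discrimination(self):
        params = pd.DataFrame({"beta": [-0.5, 0.3, 1.1], "alpha": [0.9, 1.3, 1.7]})
        tcc, _ = asm.test_curves(params, np.linspace(-4, 4, 101))
        assert (np.diff(tcc) > 0).all()


class TestReliability:
    def test_vanishing_discrimination(self):
        params = pd.DataFrame({"beta": [0.0, 0.5], "alpha": [1e-6, 1e-6]})
        assert asm.reliability(params) < 1e-6

    def test_spearman_brown_under_duplication(self):
        params = pd.DataFrame({"beta": np.linspace(-1.5, 1.5, 10),
                               "alpha": np.linspace(0.9, 1.8, 10),
                               "gamma": np.full(10, 0.25)})
        rho = asm.reliability(params)
        doubled = pd.concat([params, params], ignore_index=True)
        rho2 = asm.reliability(doubled)
        assert rho2 == pytest.approx(2 * rho / (1 + rho), abs=1e-10)

    def test_quadrature_agrees_with_monte_carlo(self):
        params = pd.DataFrame({"beta": np.linspace(-1, 1, 8),
                               "alpha": np.full(8, 1.4),
                               "gamma": np.full(8, 0.25)})
        rho_quad = asm.reliability(params, n_quad=61)
        rng = np.random.default_rng(0)
        theta = rng.standard_normal(1_000_000)
        from cloneirt.core import response_probability
        p = response_probability(theta[None, :], params["beta"].to_numpy()[:, None],
                                 params["alpha"].to_numpy()[:, None], 0.25)
        tcc = p.sum(axis=0)
        err = (p * (1 - p)).sum(axis=0)
        rho_mc = tcc.var() / (tcc.var() + err.mean())
        assert rho_quad == pytest.approx(rho_mc, abs=1e-3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            asm.reliability(pd.DataFrame(columns=["beta", "alpha"]))


class TestSolveAssembly:
    def test_matches_exhaustive_enumeration(self):
        items = _toy_bank()
        problem = asm.AssemblyProblem(items, n_forms=1, form_length=3)
        form = asm.solve_assembly(problem)[0]
        grid = np.asarray(problem.theta_grid)

        def min_tif(sel):
            s = items[items["clone_id"].isin(sel)]
            return asm.test_curves(s, grid)[1].min()

        best_val, best_sets = -np.inf, []
        for combo in itertools.combinations(items["clone_id"], 3):
            s = items[items["clone_id"].isin(combo)]
            if s["template_id"].nunique() < 3 or s["distractor_type"].nunique() > 1:
                continue
            v = min_tif(combo)
            if v > best_val + 1e-12:
                best_val, best_sets = v, [set(combo)]
            elif abs(v - best_val) <= 1e-12:
                best_sets.append(set(combo))
        assert set(form.clone_ids) in best_sets
        assert min_tif(form.clone_ids) == pytest.approx(best_val, abs=1e-9)

    def test_infeasible_length_explained(self):
        with pytest.raises(asm.AssemblyInfeasibleError, match="templates"):
            asm.solve_assembly(asm.AssemblyProblem(_toy_bank(), 1, 13))

    def test_clone_uniqueness_infeasibility(self):
        items = _toy_bank()
        with pytest.raises(asm.AssemblyInfeasibleError):
            asm.solve_assembly(asm.AssemblyProblem(items, n_forms=5, form_length=3))

    def test_constraint_audit_on_bank(self):
        study = sim.simulate_study(sim.desk_config(seed=44))
        items = study.item_params.merge(
            study.bank.clones[["clone_id", "template_id", "distractor_type"]],
            on="clone_id")
        problem = asm.AssemblyProblem(items, n_forms=3, form_length=8,
                                      shared_templates=True, time_limit_s=30)
        forms = asm.solve_assembly(problem)
        tpl_sets = []
        all_clones = []
        for f in forms:
            sel = items[items["clone_id"].isin(f.clone_ids)]
            assert len(sel) == 8
            assert sel["template_id"].nunique() == 8       # one clone/template
            assert sel["distractor_type"].nunique() == 1   # homogeneous form
            tpl_sets.append(tuple(sorted(sel["template_id"])))
            all_clones.extend(f.clone_ids)
        assert len(set(tpl_sets)) == 1                     # shared templates
        assert len(all_clones) == len(set(all_clones))     # clone uniqueness
        tifs = np.stack([f.tif for f in forms])
        gap = np.max(np.abs(tifs[:, None, :] - tifs[None, :, :]))
        assert gap <= problem.parallelism_tol + 1e-6


class TestEvaluateForms:
    def test_single_form_report(self):
        items = _toy_bank().assign(gamma=0.25)
        forms = asm.solve_assembly(asm.AssemblyProblem(items, 1, 3))
        report = asm.evaluate_forms(forms, items)
        assert len(report) == 1
        assert 0.0 <= report.loc[0, "reliability"] < 1.0
        assert report.loc[0, "expected_score_theta0"] > 3 * 0.25

    def test_parallel_forms_have_matched_reliability(self):
        # mirrored bank: each template's MD and PD clones share parameters,
        # so truly parallel forms exist and the solver should find them
        rng = np.random.default_rng(5)
        rows = []
        for t in range(6):
            beta, alpha = rng.normal(), rng.uniform(0.9, 1.8)
            rows.append((2 * t, t, "MD", beta, alpha))
            rows.append((2 * t + 1, t, "PD", beta, alpha))
        items = pd.DataFrame(rows, columns=["clone_id", "template_id",
                                            "distractor_type", "beta", "alpha"]
                             ).assign(gamma=0.25)
        forms = asm.solve_assembly(asm.AssemblyProblem(items, 2, 3))
        report = asm.evaluate_forms(forms, items)
        r = report["reliability"].to_numpy()
        assert abs(r[0] - r[1]) < 1e-2
        assert report.attrs["max_pairwise_tif_gap"] <= 0.5 + 1e-6

    def test_no_forms_rejected(self):
        with pytest.raises(ValueError):
            asm.evaluate_forms([])
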