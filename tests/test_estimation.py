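"""Exclusion rules, model specifications, and the posterior machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit, logsumexp

from cloneirt import estimation as est
from cloneirt import simulate as sim
from conftest import wave1_coefficients


def _records(rows):
    return pd.DataFrame(rows, columns=["person_id", "clone_id", "template_id",
                                       "accuracy", "rt", "timeout"])


class TestExclusions:
    def test_rapid_guessing_threshold(self):
        rows = [(1, k, 0, 1, 2.9, False) for k in range(4)]
        rows += [(1, k, 0, 1, 10.0, False) for k in range(4, 16)]
        rows += [(2, k, 0, 1, 2.9, False) for k in range(3)]
        rows += [(2, k, 0, 1, 10.0, False) for k in range(3, 16)]
        filtered, report = est.apply_exclusions(_records(rows))
        rep = report.set_index("person_id")
        assert rep.loc[1, "excluded_rapid"] and rep.loc[1, "excluded"]
        assert not rep.loc[2, "excluded"]        # three rapid trials: retained
        assert set(filtered["person_id"]) == {2}

    def test_missing_response_threshold(self):
        rows = [(1, k, 0, 0, 30.0, True) for k in range(4)]
        rows += [(1, k, 0, 1, 10.0, False) for k in range(4, 16)]
        _, report = est.apply_exclusions(_records(rows))
        assert report.set_index("person_id").loc[1, "excluded_missing"]

    def test_injected_artifacts_all_and_only_excluded(self):
        # moderate-RT regime: honest respondents essentially never cross
        # either exclusion threshold, so the generator's labels are exact
        rt_cfg = sim.RTConfig(intercept=np.log(12.0), person_sd=0.15,
                              residual_sd=0.30)
        cfg = sim.desk_config(seed=15, n_persons=250, rt=rt_cfg,
                              rapid_guess_rate=0.04, nonresponse_rate=0.02)
        study = sim.simulate_study(cfg)
        _, report = est.apply_exclusions(study.responses)
        merged = report.merge(study.injected, on="person_id")
        injected = merged["rapid_guesser"] | merged["nonresponder"]
        assert (merged["excluded"] == injected).all()


class TestSpecs:
    def test_model_numbers_and_waves(self):
        assert est.ModelSpec.from_number(1).wave == 1
        assert est.ModelSpec.from_number(3).wave == 1
        assert est.ModelSpec.from_number(4).wave == 2
        spec5 = est.ModelSpec.from_number(5)
        assert spec5.beta_clone_re and spec5.alpha_template_re and not spec5.alpha_clone_re
        with pytest.raises(ValueError):
            est.ModelSpec.from_number(7)

    def test_retained_draw_arithmetic(self):
        cfg = est.SamplerConfig(n_chains=4, n_iter=7500, n_warmup=5000)
        assert cfg.retained == 10_000


class TestPosteriorGradient:
    @pytest.mark.parametrize("model", [1, 5])
    def test_analytic_gradient_matches_finite_differences(self, model, tiny_study):
        data = est.build_fit_data(tiny_study.responses, tiny_study.bank,
                                  persons=tiny_study.persons)
        post = est._AmisPosterior(est.ModelSpec.from_number(model), data,
                                  est.PriorConfig())
        rng = np.random.default_rng(model)
        v = 0.2 * rng.normal(size=post.index.size)
        _, grad = post.logp_grad(v)
        fd = approx_fprime(v, lambda x: post.logp_grad(x)[0], 1e-6)
        assert np.max(np.abs(grad - fd) / (np.abs(fd) + 1.0)) < 1e-4


class TestFitting:
    def test_model1_recovers_intercept_within_three_sd(self):
        # data truly generated by the fixed-effects-only structure
        coeffs = wave1_coefficients(sigma_beta_clone=0.0, sigma_beta_template=0.0)
        cfg = sim.SimulationConfig(n_templates=8, n_sets=8, items_per_person=8,
                                   n_persons=150, coefficients=coeffs, seed=21)
        study = sim.simulate_study(cfg)
        fit = est.fit_amis(study.responses, study.bank, 1,
                           est.desk_sampler(seed=22), persons=study.persons)
        mu = fit.draws["mu_beta"]
        assert abs(mu.mean() - coeffs.mu_beta) < 3 * mu.std()

    def test_absent_variance_components_shrink(self, desk_study):
        # clone-level discrimination residuals absent from the generator:
        # model 6's extra scale concentrates near zero (bound from a
        # reference oracle run, with margin)
        fit6 = est.fit_amis(desk_study.responses, desk_study.bank, 6,
                            est.desk_sampler(seed=23), persons=desk_study.persons)
        assert fit6.draws["sigma_alpha_clone"].mean() < 0.35
        assert (fit6.draws["sigma_alpha_clone"].mean()
                < fit6.draws["sigma_beta_clone"].mean())

    def test_unknown_backend(self, tiny_study):
        with pytest.raises(ValueError, match="backend"):
            est.fit_amis(tiny_study.responses, tiny_study.bank, 1,
                         est.SamplerConfig(backend="nuts"))

    def test_emcee_cross_checks_hmc(self):
        # the two independent samplers agree on the fixed-effects-only
        # posterior of a miniature study (low-dimensional, no funnel)
        from conftest import wave1_coefficients
        cfg = sim.SimulationConfig(n_templates=4, n_sets=4, items_per_person=4,
                                   n_persons=30, coefficients=wave1_coefficients(),
                                   seed=88)
        mini = sim.simulate_study(cfg)
        fit_h = est.fit_amis(mini.responses, mini.bank, 1,
                             est.desk_sampler(seed=1), persons=mini.persons)
        sc = est.SamplerConfig(backend="emcee", n_iter=12000, n_warmup=7000,
                               n_draws=1500, seed=2)
        fit_e = est.fit_amis(mini.responses, mini.bank, 1, sc,
                             persons=mini.persons)
        mh, sh = fit_h.draws["mu_beta"].mean(), fit_h.draws["mu_beta"].std()
        me = fit_e.draws["mu_beta"].mean()
        assert abs(mh - me) < 0.75 * sh
        bh = fit_h.draws["beta"].mean(axis=0)
        be = fit_e.draws["beta"].mean(axis=0)
        sd = fit_h.draws["beta"].std(axis=0).mean()
        assert np.max(np.abs(bh - be)) < 1.0 * sd


class TestSummaries:
    def test_item_summary_shape_and_intervals(self, desk_fit, desk_study):
        summ = est.summarize_item_params(desk_fit, desk_study.bank,
                                         allow_unconverged=True)
        assert len(summ.clones) == len(desk_fit.data.clone_ids)
        assert (summ.clones["beta_hdi_low"] <= summ.clones["beta_mean"]).all()
        assert (summ.clones["beta_mean"] <= summ.clones["beta_hdi_high"]).all()
        names = set(summ.structure["parameter"])
        assert {"mu_beta", "mu_alpha", "sigma_beta_clone"} <= names

    def test_unconverged_fit_refused(self, desk_fit, desk_study):
        broken = est.PosteriorFit(desk_fit.model, desk_fit.sampler, desk_fit.data,
                                  desk_fit.draws, desk_fit.mode,
                                  {**desk_fit.diagnostics, "converged": False})
        with pytest.raises(est.UnconvergedFitError):
            est.summarize_item_params(broken, desk_study.bank)

    def test_hdi_on_known_distribution(self):
        rng = np.random.default_rng(0)
        lo, hi = est.hdi(rng.normal(size=200_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.04)
        assert hi == pytest.approx(1.96, abs=0.04)


class TestPointwiseLoglik:
    def test_partition_identity(self, tiny_fit):
        by_template = est.pointwise_loglik(tiny_fit, "template")
        by_response = est.pointwise_loglik(tiny_fit, "response")
        assert np.allclose(by_template.total(), by_response.total(), atol=1e-8)
        assert by_template.n_clusters == tiny_fit.data.n_templates

    def test_response_clustering_is_plain_pointwise(self, tiny_fit):
        cll = est.pointwise_loglik(tiny_fit, "response")
        assert cll.loglik.shape == (tiny_fit.n_draws, len(tiny_fit.data.y))
        assert (cll.cluster_sizes == 1).all()

    def test_unknown_cluster_definition(self, tiny_fit):
        with pytest.raises(ValueError, match="cluster"):
            est.pointwise_loglik(tiny_fit, "person")

    def test_marginal_matches_monte_carlo_oracle(self, tiny_study):
        # quadrature integral of one cluster's predictive density vs a large
        # Monte Carlo sample over the same (one-dimensional) residual prior
        fit = est.fit_amis(tiny_study.responses, tiny_study.bank, 2,
                           est.desk_sampler(seed=9), persons=tiny_study.persons)
        cll = est.pointwise_loglik(fit, "template", marginal_residuals=True,
                                   max_draws=25)
        d = fit.data
        sel = np.linspace(0, fit.n_draws - 1, 25).astype(int)
        tid = cll.cluster_ids[0]
        mask = tiny_study.responses["template_id"] == tid
        resp = tiny_study.responses[mask]
        cpos = {c: i for i, c in enumerate(d.clone_ids)}
        ppos = {p: i for i, p in enumerate(d.person_ids)}
        ci = np.array([cpos[c] for c in resp["clone_id"]])
        pi = np.array([ppos[p] for p in resp["person_id"]])
        y = resp["accuracy"].to_numpy()
        fe = (fit.draws["mu_beta"][sel][:, None]
              + fit.draws["delta_beta"][sel] @ d.design[ci].T)
        sig_t = fit.draws["sigma_beta_template"][sel]
        th = fit.draws["theta"][sel][:, pi]
        rng = np.random.default_rng(0)
        m = 100_000
        zt = rng.standard_normal(m)
        mc = np.empty(25)
        for s in range(25):
            beta = fe[s][None, :] + sig_t[s] * zt[:, None]
            p = 0.25 + 0.75 * expit(th[s][None, :] - beta)
            ll = np.where(y > 0, np.log(p), np.log1p(-p)).sum(axis=1)
            mc[s] = logsumexp(ll) - np.log(m)
        assert np.max(np.abs(mc - cll.loglik[:, 0])) < 0.1

    def test_reference_bank_keeps_full_coding(self, tiny_study):
        full = est.build_fit_data(tiny_study.responses, tiny_study.bank)
        drop = tiny_study.responses["template_id"] != tiny_study.bank.template_ids[0]
        sub = est.build_fit_data(tiny_study.responses[drop], tiny_study.bank,
                                 reference_bank=tiny_study.bank,
                                 use_observed_rt_attribute=False)
        keep = np.isin(full.clone_ids, sub.clone_ids)
        # element/rule/distractor columns identical to the full-bank coding
        assert np.allclose(full.design[keep][:, :3], sub.design[:, :3])
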