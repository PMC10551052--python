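"""Shared fixtures: small synthetic studies and one reusable posterior fit."""

import numpy as np
import pytest

from cloneirt import estimation as est
from cloneirt import simulate as sim
from cloneirt.core import StructureCoefficients


def wave1_coefficients(sigma_beta_clone=None, sigma_beta_template=None):
    """Structure with discrimination fixed at 1 (wave-1 generating process)."""
    co = sim.default_coefficients()
    return StructureCoefficients(
        mu_beta=co.mu_beta,
        mu_alpha=1.0,
        delta_beta=co.delta_beta,
        delta_alpha=np.zeros(4),
        sigma_beta_template=(co.sigma_beta_template if sigma_beta_template is None
                             else sigma_beta_template),
        sigma_beta_clone=(co.sigma_beta_clone if sigma_beta_clone is None
                          else sigma_beta_clone),
        sigma_alpha_template=0.0,
        sigma_alpha_clone=0.0,
        rho=co.rho,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """60 persons x 8 templates, wave-1 structure: quick to fit."""
    cfg = sim.SimulationConfig(n_templates=8, n_sets=8, items_per_person=8,
                               n_persons=60, coefficients=wave1_coefficients(),
                               seed=404)
    return sim.simulate_study(cfg)


@pytest.fixture(scope="session")
def desk_study():
    """Desk-scale study (16 templates x 6 clones, 150 persons)."""
    return sim.simulate_study(sim.desk_config(seed=500, n_persons=150))


@pytest.fixture(scope="session")
def desk_fit(desk_study):
    """One converged-protocol fit of the full model on the desk study."""
    return est.fit_amis(desk_study.responses, desk_study.bank, 5,
                        est.desk_sampler(seed=501), persons=desk_study.persons)


@pytest.fixture(scope="session")
def tiny_fit(tiny_study):
    """Wave-1 fit (model 3) on the tiny study; used for predictive checks."""
    return est.fit_amis(tiny_study.responses, tiny_study.bank, 3,
                        est.desk_sampler(seed=405), persons=tiny_study.persons)
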