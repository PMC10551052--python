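"""Posterior predictive checking, score-distribution validation and recovery.

Two discrepancy statistics are used.  The score-distribution chi-square
compares observed and model-expected proportions of persons at each total
score level (score levels of 0 or 1 are ignored).  The standardized
generalized dimensionality discrepancy measure (SGDDM) is the
overlap-weighted mean absolute standardized conditional covariance of item
residuals over item pairs — an index of local dependence unexplained by the
model.  For either statistic, the posterior predictive p (PPP) value is the
share of retained draws whose replicated discrepancy is at least the
realized one; PPP <= 0.05 flags misfit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .core import DEFAULT_GUESSING
from .estimation import PosteriorFit, SamplerConfig, desk_sampler, fit_amis
from .simulate import SimulationConfig, desk_config, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "DiscrepancyResult",
    "chi2_nc",
    "sgddm",
    "ppp",
    "score_distribution_check",
    "RecoveryConfig",
    "RecoveryReport",
    "parameter_recovery",
]

PPP_EXTREME = 0.05


@dataclass
class DiscrepancyResult:
    """Realized vs replicated discrepancies over posterior draws."""

    statistic: str
    realized: np.ndarray
    replicated: np.ndarray

    @property
    def ppp(self) -> float:
        return float(np.mean(self.replicated >= self.realized))

    @property
    def extreme(self) -> bool:
        return self.ppp <= PPP_EXTREME

    @property
    def mean_realized(self) -> float:
        return float(np.mean(self.realized))

    @property
    def mean_replicated(self) -> float:
        return float(np.mean(self.replicated))


# ---------------------------------------------------------------------------
# discrepancy statistics
# ---------------------------------------------------------------------------


def chi2_nc(observed: np.ndarray, expected: np.ndarray, n_persons: int,
            score_levels: np.ndarray | None = None, min_score: int = 2) -> float:
    """Pearson-type discrepancy between score-level proportion distributions.

    ``sum over retained levels of n * (o_s - e_s)**2 / e_s`` where levels
    below ``min_score`` (scores of 0 or 1 by default) are dropped from the
    sum.  Zero iff the retained distributions agree exactly.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected score distributions must align")
    if score_levels is None:
        score_levels = np.arange(len(observed))
    keep = np.asarray(score_levels) >= min_score
    o, e = observed[keep], expected[keep]
    if np.any(e <= 0):
        raise ValueError("expected proportion is zero at a retained score level")
    return float(n_persons * np.sum((o - e) ** 2 / e))


def _score_matrix_layout(person_idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Stable ordering of responses into an (n_persons x items) layout."""
    counts = np.bincount(person_idx)
    m = counts.max()
    if not np.all(counts == m):
        raise ValueError("score-distribution checks need equal item counts per person")
    order = np.argsort(person_idx, kind="stable")
    return order, int(m)


def _poisson_binomial_mean_pmf(p: np.ndarray) -> np.ndarray:
    """Mean over persons of each person's total-score pmf; p is (N, m)."""
    n, m = p.shape
    dp = np.zeros((n, m + 1))
    dp[:, 0] = 1.0
    for j in range(m):
        pj = p[:, j][:, None]
        dp[:, 1:] = dp[:, 1:] * (1.0 - pj) + dp[:, :-1] * pj
        dp[:, 0] = dp[:, 0] * (1.0 - pj[:, 0])
    return dp.mean(axis=0)


def _chi2_from_matrices(y_scores: np.ndarray, p_mat: np.ndarray, min_score: int) -> float:
    n, m = p_mat.shape
    expected = _poisson_binomial_mean_pmf(p_mat)
    observed = np.bincount(y_scores, minlength=m + 1) / n
    return chi2_nc(observed, expected, n, np.arange(m + 1), min_score)


def sgddm(y: np.ndarray, p: np.ndarray, person_idx: np.ndarray,
          item_idx: np.ndarray, min_overlap: int = 10) -> float:
    """Standardized generalized dimensionality discrepancy for one draw.

    Residuals ``y - p`` are paired across items over the persons who answered
    both; each pair's mean conditional cross-product is standardized by the
    model-implied item variances on the shared persons, and pairs are
    averaged with overlap weights.  Under the planned-missingness design the
    natural item unit is the template (each person answers one clone of it);
    clone-level pairs share almost no persons.  Requires at least one pair
    with ``min_overlap`` shared persons.
    """
    n = person_idx.max() + 1
    k = item_idx.max() + 1
    if k < 2:
        raise ValueError("SGDDM needs at least two items (no pairs otherwise)")
    mask = np.zeros((n, k))
    resid = np.zeros((n, k))
    w = np.zeros((n, k))
    mask[person_idx, item_idx] = 1.0
    resid[person_idx, item_idx] = y - p
    w[person_idx, item_idx] = p * (1.0 - p)

    overlap = mask.T @ mask
    cross = resid.T @ resid
    va = w.T @ mask
    vb = mask.T @ w
    iu = np.triu_indices(k, 1)
    c = overlap[iu]
    ok = c >= min_overlap
    if not ok.any():
        raise ValueError(f"no item pair has >= {min_overlap} shared persons")
    denom = np.sqrt(va[iu][ok] * vb[iu][ok])
    z = np.abs(cross[iu][ok]) / denom
    return float(np.sum(c[ok] * z) / np.sum(c[ok]))


# ---------------------------------------------------------------------------
# posterior predictive p values
# ---------------------------------------------------------------------------


def _draw_probabilities(fit: PosteriorFit, s: int) -> np.ndarray:
    d = fit.data
    beta = fit.draws["beta"][s][d.clone_idx]
    alpha = fit.draws["alpha"][s][d.clone_idx]
    theta = fit.draws["theta"][s][d.person_idx]
    return d.gamma + (1.0 - d.gamma) * expit(alpha * theta - beta)


def ppp(fit: PosteriorFit, statistic="chi2_nc", max_draws: int = 500,
        min_score: int = 2, min_overlap: int = 10, seed: int = 0) -> DiscrepancyResult:
    """Posterior predictive p value for a discrepancy statistic.

    For each retained draw the statistic is computed on the observed data
    (realized) and on a dataset replicated from that draw (replicated); the
    PPP value is the proportion of draws with replicated >= realized.
    ``statistic`` is ``"chi2_nc"``, ``"sgddm"`` or a callable
    ``f(y, p, person_idx, clone_idx) -> float``.
    """
    d = fit.data
    rng = np.random.default_rng(seed)
    n_draws = fit.n_draws
    if n_draws < 100:
        warnings.warn(f"only {n_draws} draws available for the PPP computation")
    use = (np.arange(n_draws) if n_draws <= max_draws
           else rng.choice(n_draws, size=max_draws, replace=False))

    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    if statistic == "chi2_nc":
        order, m = _score_matrix_layout(d.person_idx)
        y_mat = d.y[order].reshape(-1, m)
        obs_scores = y_mat.sum(axis=1).astype(int)

        def stat_pair(p_vec, y_rep):
            p_mat = p_vec[order].reshape(-1, m)
            real = _chi2_from_matrices(obs_scores, p_mat, min_score)
            rep_scores = y_rep[order].reshape(-1, m).sum(axis=1).astype(int)
            rep = _chi2_from_matrices(rep_scores, p_mat, min_score)
            return real, rep
    elif statistic == "sgddm":
        item_idx = d.tpl_of_clone[d.clone_idx]    # template-level pairing
        def stat_pair(p_vec, y_rep):
            real = sgddm(d.y, p_vec, d.person_idx, item_idx, min_overlap)
            rep = sgddm(y_rep, p_vec, d.person_idx, item_idx, min_overlap)
            return real, rep
    elif callable(statistic):
        def stat_pair(p_vec, y_rep):
            return (statistic(d.y, p_vec, d.person_idx, d.clone_idx),
                    statistic(y_rep, p_vec, d.person_idx, d.clone_idx))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    realized, replicated = [], []
    for s in use:
        p_vec = _draw_probabilities(fit, s)
        y_rep = (rng.random(len(p_vec)) < p_vec).astype(float)
        real, rep = stat_pair(p_vec, y_rep)
        realized.append(real)
        replicated.append(rep)
    return DiscrepancyResult(name, np.asarray(realized), np.asarray(replicated))


# ---------------------------------------------------------------------------
# validation-study score-distribution check
# ---------------------------------------------------------------------------


def score_distribution_check(new_responses: pd.DataFrame, item_params: pd.DataFrame,
                             n_draws: int = 1000, grid: np.ndarray | None = None,
                             min_score: int = 2, gamma_default: float = DEFAULT_GUESSING,
                             seed: int = 0) -> DiscrepancyResult:
    """Check a new sample's total scores against fixed item parameters.

    Two steps: per-person posteriors of latent ability under the 3PL with the
    supplied (calibration) item parameters and a Normal(0, 1) prior are
    computed by dense quadrature over an ability grid; abilities are then
    drawn from those posteriors, predicted responses simulated, and the
    score-distribution chi-square PPP computed.
    """
    if len(new_responses) == 0:
        raise ValueError("empty response set")
    params = item_params.set_index("clone_id")
    unknown = set(new_responses["clone_id"]) - set(params.index)
    if unknown:
        raise ValueError(f"responses reference unknown clones: {sorted(unknown)[:5]}")
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 81)

    person_ids, person_idx = np.unique(new_responses["person_id"], return_inverse=True)
    order, m = _score_matrix_layout(person_idx)
    resp = new_responses.iloc[order]
    y_mat = resp["accuracy"].to_numpy(dtype=float).reshape(-1, m)
    beta = params.loc[resp["clone_id"], "beta"].to_numpy().reshape(-1, m)
    alpha = params.loc[resp["clone_id"], "alpha"].to_numpy().reshape(-1, m)
    if "gamma" in params.columns:
        gam = params.loc[resp["clone_id"], "gamma"].to_numpy().reshape(-1, m)
    else:
        gam = np.full_like(beta, gamma_default)

    # person-wise ability posterior on the grid
    p_grid = gam[..., None] + (1.0 - gam[..., None]) * expit(
        alpha[..., None] * grid[None, None, :] - beta[..., None]
    )  # (N, m, G)
    loglik = np.sum(
        y_mat[..., None] * np.log(p_grid) + (1.0 - y_mat[..., None]) * np.log1p(-p_grid),
        axis=1,
    )
    logpost = loglik + norm.logpdf(grid)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    n = len(person_ids)
    cdf = np.cumsum(post, axis=1)
    obs_scores = y_mat.sum(axis=1).astype(int)
    realized, replicated = [], []
    for _ in range(n_draws):
        u = rng.random((n, 1))
        gi = (u > cdf).sum(axis=1)
        theta = grid[gi]
        p_mat = gam + (1.0 - gam) * expit(alpha * theta[:, None] - beta)
        realized.append(_chi2_from_matrices(obs_scores, p_mat, min_score))
        y_rep = (rng.random(p_mat.shape) < p_mat).astype(float)
        rep_scores = y_rep.sum(axis=1).astype(int)
        replicated.append(_chi2_from_matrices(rep_scores, p_mat, min_score))
    return DiscrepancyResult("chi2_nc", np.asarray(realized), np.asarray(replicated))


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryConfig:
    """Replicated generate-fit-compare study of parameter recovery."""

    n_replicates: int = 10
    model_number: int = 5
    simulation: SimulationConfig = field(default_factory=desk_config)
    sampler: SamplerConfig = field(default_factory=desk_sampler)
    interval_prob: float = 0.95
    seed: int = 0


@dataclass
class RecoveryReport:
    replicates: pd.DataFrame
    n_unconverged: int
    config: RecoveryConfig

    def aggregate(self) -> dict:
        agg = self.replicates.drop(columns=["replicate"]).mean().to_dict()
        agg["n_replicates"] = len(self.replicates)
        agg["n_unconverged"] = self.n_unconverged
        return agg


def parameter_recovery(config: RecoveryConfig) -> RecoveryReport:
    """Generate artificial datasets, refit, and score parameter recovery.

    Each replicate draws a fresh study (bank, persons, responses) at the
    configured scale, fits the configured model with the generative person
    covariates, and records bias, RMSE, true-vs-estimated correlation and
    central-interval coverage for the clone difficulty and discrimination
    parameters, plus recovery of the structure coefficients.  Unconverged
    replicates are excluded from the table and counted.
    """
    from dataclasses import replace as _replace

    rows = []
    n_unconverged = 0
    lo_q = (1.0 - config.interval_prob) / 2.0
    hi_q = 1.0 - lo_q
    for rep in range(config.n_replicates):
        sim_cfg = _replace(config.simulation, seed=config.seed + 1000 * rep)
        study = simulate_study(sim_cfg)
        sampler = _replace(config.sampler, seed=config.seed + 1000 * rep + 1)
        fit = fit_amis(study.responses, study.bank, config.model_number,
                       sampler_config=sampler, persons=study.persons)
        if not fit.converged:
            n_unconverged += 1
            logger.warning("recovery replicate %d unconverged; excluded", rep)
            continue
        truth = study.item_params.set_index("clone_id").loc[fit.data.clone_ids]
        row = {"replicate": rep}
        for name in ("beta", "alpha"):
            true = truth[name].to_numpy()
            draws = fit.draws[name]
            est = draws.mean(axis=0)
            lo = np.quantile(draws, lo_q, axis=0)
            hi = np.quantile(draws, hi_q, axis=0)
            row[f"{name}_bias"] = float(np.mean(est - true))
            row[f"{name}_rmse"] = float(np.sqrt(np.mean((est - true) ** 2)))
            row[f"{name}_corr"] = float(np.corrcoef(true, est)[0, 1])
            row[f"{name}_coverage"] = float(np.mean((true >= lo) & (true <= hi)))
        coeffs = sim_cfg.coefficients
        row["mu_beta_err"] = float(fit.draws["mu_beta"].mean() - coeffs.mu_beta)
        row["rho_rmse"] = float(np.sqrt(np.mean(
            (fit.draws["rho"].mean(axis=0) - coeffs.rho) ** 2)))
        d_est = fit.draws["delta_beta"].mean(axis=0)
        row["delta_beta_rmse"] = float(np.sqrt(np.mean((d_est - coeffs.delta_beta) ** 2)))
        rows.append(row)
    return RecoveryReport(pd.DataFrame(rows), n_unconverged, config)
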