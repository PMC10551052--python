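"""Synthetic calibration studies with the sampling design of the item bank.

Generates complete artificial datasets — an item bank of templates x clones,
persons with covariate-structured abilities, a stratified/counterbalanced
assignment of items to persons, and accuracy + response-time records — so the
whole estimation/checking/assembly pipeline is testable without any external
download.  The generator's defaults reproduce the calibration study's
conditions: 64 templates x 6 clones (3 shape sets x 2 distractor types),
~1500 persons each answering 16 of 64 templates (one per difficulty set),
responses from the additive-structure 3PL with guessing fixed at 0.25, and
log response times with a person random intercept, the accuracy x rest-score
x difficulty fixed-effect structure, and 30-s censoring (censored trials
flagged as timeouts and coded incorrect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import (
    DEFAULT_GUESSING,
    ALPHA_BOUNDS,
    ItemBank,
    ResidualDraws,
    StructureCoefficients,
    ability_residual_scale,
    compose_difficulty,
    compose_discrimination,
    orthogonalize_attribute,
    response_probability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RTConfig",
    "SimulationConfig",
    "SimulatedStudy",
    "default_coefficients",
    "desk_config",
    "generate_item_bank",
    "generate_persons",
    "assign_items",
    "simulate_responses",
    "simulate_study",
]

# posterior-mean structure estimated in the calibration study; these are the
# generative study conditions, not tuning knobs
DEFAULT_MU_BETA = 0.177
DEFAULT_MU_ALPHA = 1.298
DEFAULT_DELTA_BETA = (0.579, 0.514, 1.105, 0.541)   # element, rule, distractor, rt
DEFAULT_DELTA_ALPHA = (-0.015, 0.020, -0.029, -0.010)
DEFAULT_SIGMA_BETA_CLONE = 0.620
DEFAULT_SIGMA_ALPHA_TEMPLATE = 0.221
DEFAULT_RHO = (-0.299, 0.128, 0.427, 0.368)          # age, gender, mean RT, delta RT
DEFAULT_TOTAL_BETA_SD = 1.431

# distributions of template complexity attributes (element 1-4 median 2,
# rule 1-6 median 3, drawn independently)
ELEMENT_LEVELS = np.array([1, 2, 3, 4])
ELEMENT_PROBS = np.array([0.30, 0.35, 0.20, 0.15])
RULE_LEVELS = np.array([1, 2, 3, 4, 5, 6])
RULE_PROBS = np.array([0.10, 0.20, 0.25, 0.20, 0.15, 0.10])

#: scale of the exogenous clone-level mean-log-RT attribute (log seconds)
RT_ATTRIBUTE_SD = 0.15


@dataclass
class RTConfig:
    """Generative model for log response times (seconds).

    ``log RT = intercept + fixed effects + clone offset + person intercept +
    noise``, censored at ``censor_s``.  The seven fixed-effect defaults are
    the calibration study's mixed-model coefficients for centered accuracy,
    standardized rest score, standardized item difficulty and their
    interactions; intercept log(15) s and the two variance components were
    chosen to give a mean response time of roughly 16 s with realistic
    person-to-person spread.
    """

    intercept: float = float(np.log(15.0))
    person_sd: float = 0.25
    residual_sd: float = 0.35
    accuracy: float = 0.039
    score: float = 0.167
    difficulty: float = 0.073
    accuracy_score: float = -0.064
    accuracy_difficulty: float = 0.097
    score_difficulty: float = 0.032
    accuracy_score_difficulty: float = 0.012
    censor_s: float = 30.0
    #: share of would-be-overtime trials answered just before the deadline
    #: (per the task instructions to guess at the buzzer); the rest time out
    deadline_guess_prob: float = 0.75

    def coefficient_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "score": self.score,
            "difficulty": self.difficulty,
            "accuracy:score": self.accuracy_score,
            "accuracy:difficulty": self.accuracy_difficulty,
            "score:difficulty": self.score_difficulty,
            "accuracy:score:difficulty": self.accuracy_score_difficulty,
        }


def default_coefficients(
    sigma_beta_template: float | None = None,
    target_beta_sd: float = DEFAULT_TOTAL_BETA_SD,
) -> StructureCoefficients:
    """Calibration-study structure coefficients.

    The template-level difficulty residual scale is solved analytically so
    that the marginal sd of difficulty over a large bank matches
    ``target_beta_sd``:  Var(beta) = Var(fixed effects) + sigma_t^2 +
    sigma_c^2 under the generator's attribute distributions.
    """
    delta_beta = np.asarray(DEFAULT_DELTA_BETA)
    if sigma_beta_template is None:
        var_el = float(np.sum(ELEMENT_PROBS * ELEMENT_LEVELS**2)
                       - np.sum(ELEMENT_PROBS * ELEMENT_LEVELS) ** 2)
        var_ru = float(np.sum(RULE_PROBS * RULE_LEVELS**2)
                       - np.sum(RULE_PROBS * RULE_LEVELS) ** 2)
        var_fe = (
            delta_beta[0] ** 2 * var_el
            + delta_beta[1] ** 2 * var_ru
            + delta_beta[2] ** 2 * 0.25            # centered +/-0.5 distractor code
            + delta_beta[3] ** 2 * RT_ATTRIBUTE_SD**2
        )
        resid = target_beta_sd**2 - var_fe - DEFAULT_SIGMA_BETA_CLONE**2
        if resid <= 0:
            raise ValueError("attribute variance already exceeds the target difficulty sd")
        sigma_beta_template = float(np.sqrt(resid))
    return StructureCoefficients(
        mu_beta=DEFAULT_MU_BETA,
        mu_alpha=DEFAULT_MU_ALPHA,
        delta_beta=delta_beta,
        delta_alpha=np.asarray(DEFAULT_DELTA_ALPHA),
        sigma_beta_template=sigma_beta_template,
        sigma_beta_clone=DEFAULT_SIGMA_BETA_CLONE,
        sigma_alpha_template=DEFAULT_SIGMA_ALPHA_TEMPLATE,
        sigma_alpha_clone=0.0,   # best-supported structure: no clone-level alpha residual
        rho=np.asarray(DEFAULT_RHO),
    )


@dataclass
class SimulationConfig:
    """Design and statistical parameters of one synthetic calibration study."""

    n_templates: int = 64
    clones_per_template: int = 6
    n_persons: int = 1501
    n_sets: int = 16
    items_per_person: int = 16
    coefficients: StructureCoefficients = field(default_factory=default_coefficients)
    rt: RTConfig = field(default_factory=RTConfig)
    guessing: float = DEFAULT_GUESSING
    rapid_guess_rate: float = 0.0
    nonresponse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates % self.n_sets:
            raise ValueError("n_templates must be divisible by n_sets")
        if self.items_per_person != self.n_sets:
            raise ValueError("items_per_person must equal n_sets (one item per set)")
        if self.clones_per_template != 6:
            raise ValueError("a full bank has 6 clones per template (3 shape sets x 2 distractor types)")


def desk_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Down-scaled study (16 templates, 300 persons) for fast desk runs."""
    base = dict(n_templates=16, n_persons=300, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SimulatedStudy:
    """A complete synthetic study with its ground truth attached."""

    config: SimulationConfig
    bank: ItemBank
    item_params: pd.DataFrame
    residuals: ResidualDraws
    persons: pd.DataFrame
    assignment: pd.DataFrame
    responses: pd.DataFrame
    injected: pd.DataFrame


# ---------------------------------------------------------------------------
# item bank
# ---------------------------------------------------------------------------


def generate_item_bank(config: SimulationConfig, rng: np.random.Generator
                       ) -> tuple[ItemBank, pd.DataFrame, ResidualDraws]:
    """Draw a bank of templates/clones and realize their true 3PL parameters.

    Discrimination values falling outside the admissible [0, 5] range are
    handled by redrawing the offending residuals (rare at default scales);
    the number of redraws is logged.
    """
    coeffs = config.coefficients
    n_t = config.n_templates
    n_c = n_t * config.clones_per_template

    element = rng.choice(ELEMENT_LEVELS, size=n_t, p=ELEMENT_PROBS)
    rule = rng.choice(RULE_LEVELS, size=n_t, p=RULE_PROBS)
    # monotone complexity index of the (element, rule) quantiles, used only to
    # stratify templates into sets of comparable difficulty
    quant = rankdata(element, method="average") + rankdata(rule, method="average")
    dimensionality = rankdata(quant, method="ordinal").astype(int)

    rows = []
    cid = 0
    for tid in range(n_t):
        for shape in (1, 2, 3):
            for dist in ("MD", "PD"):
                rows.append((cid, tid, shape, dist, element[tid], rule[tid], dimensionality[tid]))
                cid += 1
    clones = pd.DataFrame(
        rows,
        columns=["clone_id", "template_id", "shape_set", "distractor_type",
                 "element_n", "rule_n", "dimensionality"],
    )

    # exogenous clone dwell-time offsets; their orthogonalized version is the
    # RT attribute entering the item structure, the raw version feeds the RT
    # simulation so a refit from simulated data can recover the attribute
    rt_offset = rng.normal(0.0, RT_ATTRIBUTE_SD, size=n_c)
    bank = ItemBank(clones.assign(rt_offset=rt_offset))
    q, _ = bank.design_matrices(center=True)
    dist_code = bank.design_matrices(center=True)[1][:, 0]
    rt_orth = orthogonalize_attribute(rt_offset, np.column_stack([q, dist_code]))
    bank = bank.with_rt_attribute(rt_orth)
    q, r = bank.design_matrices(center=True)
    tpl_idx = bank.template_index()

    eps_bt = rng.normal(0.0, coeffs.sigma_beta_template, size=n_t)
    eps_bc = rng.normal(0.0, coeffs.sigma_beta_clone, size=n_c)
    eps_at = rng.normal(0.0, coeffs.sigma_alpha_template, size=n_t)
    eps_ac = rng.normal(0.0, coeffs.sigma_alpha_clone, size=n_c)

    beta = compose_difficulty(coeffs, q, r, eps_bt[tpl_idx], eps_bc)
    alpha = np.asarray(
        compose_discrimination(coeffs, q, r, eps_at[tpl_idx], eps_ac,
                               on_out_of_bounds="ignore")
    )
    lo, hi = ALPHA_BOUNDS
    n_redraws = 0
    while True:
        bad = (alpha < lo) | (alpha > hi)
        if not bad.any() or n_redraws >= 1000:
            break
        n_redraws += int(bad.sum())
        bad_t = np.unique(tpl_idx[bad])
        eps_at[bad_t] = rng.normal(0.0, coeffs.sigma_alpha_template, size=len(bad_t))
        if coeffs.sigma_alpha_clone > 0:
            eps_ac[bad] = rng.normal(0.0, coeffs.sigma_alpha_clone, size=int(bad.sum()))
        alpha = np.asarray(
            compose_discrimination(coeffs, q, r, eps_at[tpl_idx], eps_ac,
                                   on_out_of_bounds="ignore")
        )
    if n_redraws:
        logger.info("redrew %d out-of-bounds discrimination residual(s)", n_redraws)
    alpha = np.clip(alpha, lo, hi)

    params = pd.DataFrame(
        {"clone_id": bank.clones["clone_id"], "beta": beta, "alpha": alpha,
         "gamma": config.guessing}
    )
    residuals = ResidualDraws(eps_bt, eps_bc, eps_at, eps_ac)
    return bank, params, residuals


# ---------------------------------------------------------------------------
# persons
# ---------------------------------------------------------------------------


def generate_persons(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw persons with standardized covariates and structured abilities.

    Age, mean-RT and delta-RT covariates are standard-scored over the sample;
    gender is balanced and binary coded (male = -0.5, female = +0.5).  Ability
    is ``theta = X @ rho + eps`` with ``eps ~ Normal(0, 1 - sum(rho**2))``.
    """
    n = config.n_persons
    rho = config.coefficients.rho

    def _z(x):
        return (x - x.mean()) / x.std()

    age = _z(rng.normal(size=n))
    gender = np.where(np.arange(n) % 2 == 0, -0.5, 0.5)
    rng.shuffle(gender)
    mean_rt = _z(rng.normal(size=n))
    delta_rt = _z(rng.normal(size=n))
    x = np.column_stack([age, gender, mean_rt, delta_rt])
    eps = rng.normal(0.0, ability_residual_scale(rho), size=n)
    theta = x @ rho + eps
    return pd.DataFrame(
        {"person_id": np.arange(n), "age_z": age, "gender_code": gender,
         "mean_rt_z": mean_rt, "delta_rt_z": delta_rt, "theta": theta}
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def assign_items(bank: ItemBank, persons: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Stratified template selection with counterbalanced clone assignment.

    Templates are sorted by dimensionality and split into ``n_sets`` sets;
    each person receives one pseudorandomly selected template per set (so all
    test forms have comparable difficulty).  Within a template, successive
    administrations cycle through a random permutation of its six clones,
    keeping per-clone administration counts near-uniform.
    """
    per_set = config.n_templates // config.n_sets
    tpl = bank.templates.sort_values(["dimensionality", "template_id"])
    sets = tpl["template_id"].to_numpy().reshape(config.n_sets, per_set)

    clone_lookup = {
        tid: grp["clone_id"].to_numpy()
        for tid, grp in bank.clones.groupby("template_id")
    }
    n_var = config.clones_per_template
    perms = {tid: rng.permutation(n_var) for tid in clone_lookup}
    counters = {tid: 0 for tid in clone_lookup}

    records = []
    for pid in persons["person_id"].to_numpy():
        chosen = sets[np.arange(config.n_sets), rng.integers(0, per_set, size=config.n_sets)]
        order = rng.permutation(config.n_sets)
        for set_idx, tid in enumerate(chosen):
            k = counters[tid]
            clone = clone_lookup[tid][perms[tid][k % n_var]]
            counters[tid] = k + 1
            records.append((pid, set_idx, tid, clone, order[set_idx]))
    return pd.DataFrame(
        records, columns=["person_id", "set_index", "template_id", "clone_id", "order"]
    )


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------


def simulate_responses(assignment: pd.DataFrame, item_params: pd.DataFrame,
                       persons: pd.DataFrame, rt_config: RTConfig,
                       rng: np.random.Generator, bank: ItemBank | None = None,
                       rapid_guess_rate: float = 0.0, nonresponse_rate: float = 0.0,
                       guessing: float = DEFAULT_GUESSING,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate accuracy and censored response times for an assignment table.

    Accuracy is Bernoulli under the 3PL; log RT follows the mixed-model
    structure with centered accuracy, standardized rest score and
    standardized empirical item difficulty (one minus proportion correct).
    Trials whose latent time overruns the deadline are mostly answered just
    before it (participants are instructed to guess at the buzzer; accuracy
    unchanged), the rest are censored at the deadline, flagged as timeouts
    and coded incorrect.  Optionally injects rapid-guessing and
    non-responding persons at the given rates; returns
    ``(responses, injected_labels)``.
    """
    df = assignment.merge(item_params, on="clone_id", how="left", validate="many_to_one")
    if df["beta"].isna().any():
        missing = sorted(df.loc[df["beta"].isna(), "clone_id"].unique())
        raise ValueError(f"no item parameters for assigned clones: {missing}")
    df = df.merge(persons[["person_id", "theta"]], on="person_id", how="left")

    p = response_probability(df["theta"], df["beta"], df["alpha"], gamma=guessing)
    acc = (rng.random(len(df)) < p).astype(int)
    df["accuracy"] = acc

    # empirical item difficulty and rest scores, as in the RT analysis
    prop_correct = df.groupby("clone_id")["accuracy"].transform("mean")
    difficulty = 1.0 - prop_correct
    total = df.groupby("person_id")["accuracy"].transform("sum")
    rest = total - df["accuracy"]

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    a_c = df["accuracy"] - df["accuracy"].mean()
    s_z = _z(rest)
    d_z = _z(difficulty)

    c = rt_config
    log_rt = (
        c.intercept
        + c.accuracy * a_c + c.score * s_z + c.difficulty * d_z
        + c.accuracy_score * a_c * s_z + c.accuracy_difficulty * a_c * d_z
        + c.score_difficulty * s_z * d_z
        + c.accuracy_score_difficulty * a_c * s_z * d_z
    )
    if bank is not None and "rt_offset" in bank.clones.columns:
        offset = bank.clones.set_index("clone_id")["rt_offset"]
        log_rt = log_rt + df["clone_id"].map(offset).to_numpy()
    person_ids = persons["person_id"].to_numpy()
    u = pd.Series(rng.normal(0.0, c.person_sd, size=len(person_ids)), index=person_ids)
    log_rt = log_rt + df["person_id"].map(u).to_numpy()
    log_rt = log_rt + rng.normal(0.0, c.residual_sd, size=len(df))

    rt = np.exp(log_rt.to_numpy())
    if np.isfinite(c.censor_s):
        overtime = rt >= c.censor_s
        buzzer = overtime & (rng.random(len(rt)) < c.deadline_guess_prob)
        rt[buzzer] = rng.uniform(c.censor_s - 2.0, c.censor_s, size=int(buzzer.sum()))
        timeout = overtime & ~buzzer
        rt = np.minimum(rt, c.censor_s)
    else:
        timeout = np.zeros(len(rt), dtype=bool)
    df["rt"] = rt
    df["timeout"] = timeout
    df.loc[timeout, "accuracy"] = 0   # censored trials coded incorrect

    # artifact injection: disjoint sets of rapid guessers and non-responders
    n = len(person_ids)
    shuffled = rng.permutation(person_ids)
    n_rapid = int(round(rapid_guess_rate * n))
    n_miss = int(round(nonresponse_rate * n))
    rapid_persons = set(shuffled[:n_rapid])
    miss_persons = set(shuffled[n_rapid:n_rapid + n_miss])

    for pid in rapid_persons:
        idx = df.index[df["person_id"] == pid].to_numpy()
        k = int(rng.integers(4, len(idx) + 1))
        pick = rng.choice(idx, size=k, replace=False)
        df.loc[pick, "rt"] = rng.uniform(0.3, 3.0, size=k)
        df.loc[pick, "accuracy"] = (rng.random(k) < guessing).astype(int)
        df.loc[pick, "timeout"] = False
    for pid in miss_persons:
        idx = df.index[df["person_id"] == pid].to_numpy()
        k = int(rng.integers(4, len(idx) + 1))
        pick = rng.choice(idx, size=k, replace=False)
        df.loc[pick, "rt"] = c.censor_s
        df.loc[pick, "timeout"] = True
        df.loc[pick, "accuracy"] = 0

    injected = pd.DataFrame(
        {"person_id": person_ids,
         "rapid_guesser": [pid in rapid_persons for pid in person_ids],
         "nonresponder": [pid in miss_persons for pid in person_ids]}
    )
    cols = ["person_id", "set_index", "template_id", "clone_id", "order",
            "accuracy", "rt", "timeout"]
    return df[cols].copy(), injected


# ---------------------------------------------------------------------------
# one-call study
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete study with hierarchical substreams per stage.

    A single global seed is split with :class:`numpy.random.SeedSequence`
    into independent substreams for the bank, the persons, the assignment and
    the responses, so each stage is individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_bank, rng_pers, rng_assign, rng_resp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    bank, params, residuals = generate_item_bank(config, rng_bank)
    persons = generate_persons(config, rng_pers)
    assignment = assign_items(bank, persons, config, rng_assign)
    responses, injected = simulate_responses(
        assignment, params, persons, config.rt, rng_resp, bank=bank,
        rapid_guess_rate=config.rapid_guess_rate,
        nonresponse_rate=config.nonresponse_rate,
        guessing=config.guessing,
    )
    return SimulatedStudy(config, bank, params, residuals, persons, assignment,
                          responses, injected)
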