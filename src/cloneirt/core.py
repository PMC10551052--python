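"""Domain types and deterministic mathematics of the clone-structured 3PL model.

The measurement model is a three-parameter logistic (3PL) item response model
in which item clones are nested within item templates.  The probability that
person *i* answers clone *k* (of template *j*) correctly is

    p = gamma + (1 - gamma) * logistic(alpha * theta_i - beta_jk)

with difficulty ``beta`` and discrimination ``alpha`` decomposed additively
into an intercept, fixed effects of template-level attributes (element number,
rule number), fixed effects of clone-level attributes (distractor type,
orthogonalized mean log response time), and residuals at the template and the
clone level.  Latent ability is regressed on standardized person covariates
(age, gender, mean response time, response-time slowing on hard items), with
the residual ability variance fixed at ``1 - sum(rho**2)`` so that the
marginal ability variance is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ATTRIBUTE_NAMES",
    "TEMPLATE_ATTRIBUTES",
    "CLONE_ATTRIBUTES",
    "DISTRACTOR_CODES",
    "ItemTemplate",
    "ItemClone",
    "Person",
    "ResidualDraws",
    "StructureCoefficients",
    "ItemParams",
    "ItemBank",
    "response_probability",
    "compose_difficulty",
    "compose_discrimination",
    "compose_ability",
    "ability_residual_scale",
    "orthogonalize_attribute",
    "marginal_attribute_effect",
]

#: order of the attribute fixed-effect vectors delta_beta / delta_alpha
TEMPLATE_ATTRIBUTES = ("element", "rule")
CLONE_ATTRIBUTES = ("distractor", "rt")
ATTRIBUTE_NAMES = TEMPLATE_ATTRIBUTES + CLONE_ATTRIBUTES

#: centered coding of distractor type: minimal-difference (MD) clones are
#: harder, paired-difference (PD) clones easier; centered so the intercept
#: mu_beta keeps its "average difficulty across items" reading.
DISTRACTOR_CODES = {"MD": 0.5, "PD": -0.5}

ALPHA_BOUNDS = (0.0, 5.0)
DEFAULT_GUESSING = 0.25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemTemplate:
    """A base puzzle design; clones inherit its complexity attributes."""

    template_id: int
    element_n: int
    rule_n: int
    dimensionality: int

    def __post_init__(self) -> None:
        if not 1 <= self.element_n <= 4:
            raise ValueError(f"element_n must be in [1, 4], got {self.element_n}")
        if not 1 <= self.rule_n <= 6:
            raise ValueError(f"rule_n must be in [1, 6], got {self.rule_n}")


@dataclass(frozen=True)
class ItemClone:
    """A perceptual/distractor variant of a template (equal complexity)."""

    clone_id: int
    template_id: int
    shape_set: int
    distractor_type: str
    mean_log_rt_orth: float = 0.0

    def __post_init__(self) -> None:
        if self.shape_set not in (1, 2, 3):
            raise ValueError(f"shape_set must be 1, 2 or 3, got {self.shape_set}")
        if self.distractor_type not in DISTRACTOR_CODES:
            raise ValueError(
                f"distractor_type must be one of {sorted(DISTRACTOR_CODES)}, "
                f"got {self.distractor_type!r}"
            )


@dataclass(frozen=True)
class Person:
    """A test taker with standardized covariates and latent ability.

    Gender is binary coded (male = -0.5, female = +0.5); the remaining
    covariates are standard-scored over the analysis sample.
    """

    person_id: int
    age_z: float
    gender_code: float
    mean_rt_z: float
    delta_rt_z: float
    theta: float

    def __post_init__(self) -> None:
        if self.gender_code not in (-0.5, 0.5):
            raise ValueError(f"gender_code must be -0.5 or +0.5, got {self.gender_code}")

    @property
    def covariates(self) -> np.ndarray:
        return np.array([self.age_z, self.gender_code, self.mean_rt_z, self.delta_rt_z])


@dataclass
class ResidualDraws:
    """Template- and clone-level residuals of the additive item structure."""

    eps_beta_template: np.ndarray
    eps_beta_clone: np.ndarray
    eps_alpha_template: np.ndarray
    eps_alpha_clone: np.ndarray

    @classmethod
    def zeros(cls, n_templates: int, n_clones: int) -> "ResidualDraws":
        return cls(
            np.zeros(n_templates),
            np.zeros(n_clones),
            np.zeros(n_templates),
            np.zeros(n_clones),
        )


@dataclass
class StructureCoefficients:
    """Fixed effects and residual scales of the additive item structure.

    ``delta_beta`` / ``delta_alpha`` are ordered as :data:`ATTRIBUTE_NAMES`:
    (element, rule, distractor, rt).  ``rho`` holds the person-covariate
    coefficients (age, gender, mean RT, delta RT); the residual ability
    variance is ``1 - sum(rho**2)`` and must be positive.
    """

    mu_beta: float = 0.0
    mu_alpha: float = 1.0
    delta_beta: np.ndarray = field(default_factory=lambda: np.zeros(4))
    delta_alpha: np.ndarray = field(default_factory=lambda: np.zeros(4))
    sigma_beta_template: float = 0.0
    sigma_beta_clone: float = 0.0
    sigma_alpha_template: float = 0.0
    sigma_alpha_clone: float = 0.0
    rho: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        self.delta_beta = np.asarray(self.delta_beta, dtype=float)
        self.delta_alpha = np.asarray(self.delta_alpha, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.delta_beta.shape != (len(ATTRIBUTE_NAMES),):
            raise ValueError("delta_beta must have one entry per attribute")
        if self.delta_alpha.shape != (len(ATTRIBUTE_NAMES),):
            raise ValueError("delta_alpha must have one entry per attribute")
        for name in (
            "sigma_beta_template",
            "sigma_beta_clone",
            "sigma_alpha_template",
            "sigma_alpha_clone",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if np.sum(self.rho**2) >= 1.0:
            raise ValueError(
                "sum(rho**2) must be < 1 so residual ability variance is positive"
            )

    @property
    def residual_ability_variance(self) -> float:
        return float(1.0 - np.sum(self.rho**2))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("delta_beta", "delta_alpha", "rho"):
            d[key] = list(np.asarray(d[key], dtype=float))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StructureCoefficients":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StructureCoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ItemParams:
    """Realized 3PL parameters of one item clone."""

    clone_id: int
    beta: float
    alpha: float
    gamma: float = DEFAULT_GUESSING

    def __post_init__(self) -> None:
        lo, hi = ALPHA_BOUNDS
        if not lo <= self.alpha <= hi:
            raise ValueError(f"alpha must lie in [{lo}, {hi}], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")


class ItemBank:
    """Registry of item templates and their clones.

    Wraps a clone-level :class:`pandas.DataFrame` with columns ``clone_id``,
    ``template_id``, ``shape_set``, ``distractor_type``, ``element_n``,
    ``rule_n``, ``dimensionality`` and (optionally) ``mean_log_rt_orth``.
    A *full* bank has exactly six clones per template: the crossing of three
    shape sets with two distractor types.
    """

    REQUIRED_COLUMNS = (
        "clone_id",
        "template_id",
        "shape_set",
        "distractor_type",
        "element_n",
        "rule_n",
        "dimensionality",
    )

    def __init__(self, clones: pd.DataFrame, require_full: bool = True):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in clones.columns]
        if missing:
            raise ValueError(f"item bank is missing columns: {missing}")
        clones = clones.sort_values("clone_id").reset_index(drop=True)
        if clones["clone_id"].duplicated().any():
            raise ValueError("clone ids must be unique")
        bad = ~clones["distractor_type"].isin(list(DISTRACTOR_CODES))
        if bad.any():
            raise ValueError(
                f"unknown distractor types: {sorted(clones.loc[bad, 'distractor_type'].unique())}"
            )
        if not clones["element_n"].between(1, 4).all():
            raise ValueError("element_n outside [1, 4]")
        if not clones["rule_n"].between(1, 6).all():
            raise ValueError("rule_n outside [1, 6]")
        if require_full:
            for tid, grp in clones.groupby("template_id"):
                cells = set(zip(grp["shape_set"], grp["distractor_type"]))
                if len(grp) != 6 or len(cells) != 6:
                    raise ValueError(
                        f"template {tid} must have 6 clones crossing "
                        "3 shape sets x 2 distractor types"
                    )
        if "mean_log_rt_orth" not in clones.columns:
            clones = clones.assign(mean_log_rt_orth=0.0)
        self.clones = clones

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def n_templates(self) -> int:
        return self.clones["template_id"].nunique()

    @property
    def template_ids(self) -> np.ndarray:
        return np.sort(self.clones["template_id"].unique())

    @property
    def templates(self) -> pd.DataFrame:
        cols = ["template_id", "element_n", "rule_n", "dimensionality"]
        return (
            self.clones[cols].drop_duplicates("template_id")
            .sort_values("template_id")
            .reset_index(drop=True)
        )

    def template_index(self) -> np.ndarray:
        """Position of each clone's template in ``template_ids`` order."""
        order = {tid: i for i, tid in enumerate(self.template_ids)}
        return self.clones["template_id"].map(order).to_numpy()

    def design_matrices(self, center: bool = True):
        """Attribute design matrices for the additive item structure.

        Returns ``(Q, R)`` where ``Q`` (clones x 2) holds the template-level
        attributes (element number, rule number; mean-centered over clones by
        default) and ``R`` (clones x 2) the clone-level attributes (centered
        distractor code, orthogonalized mean log RT).
        """
        q = self.clones[["element_n", "rule_n"]].to_numpy(dtype=float)
        if center:
            q = q - q.mean(axis=0)
        dist = self.clones["distractor_type"].map(DISTRACTOR_CODES).to_numpy(dtype=float)
        r = np.column_stack([dist, self.clones["mean_log_rt_orth"].to_numpy(dtype=float)])
        return q, r

    def with_rt_attribute(self, mean_log_rt_orth: np.ndarray) -> "ItemBank":
        clones = self.clones.assign(mean_log_rt_orth=np.asarray(mean_log_rt_orth, float))
        return ItemBank(clones, require_full=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def response_probability(theta, beta, alpha=1.0, gamma=DEFAULT_GUESSING):
    """3PL probability of a correct response.

    ``p = gamma + (1 - gamma) * logistic(alpha * theta - beta)``.  All
    arguments broadcast; the result lies strictly inside ``(gamma, 1)`` and is
    increasing in ``theta`` whenever ``alpha > 0``.
    """
    theta, beta, alpha = np.asarray(theta, float), np.asarray(beta, float), np.asarray(alpha, float)
    return gamma + (1.0 - gamma) * expit(alpha * theta - beta)


def _compose(mu, delta, q_row, r_row, eps_template, eps_clone):
    q_row = np.atleast_2d(np.asarray(q_row, dtype=float))
    r_row = np.atleast_2d(np.asarray(r_row, dtype=float))
    n_t, n_c = len(TEMPLATE_ATTRIBUTES), len(CLONE_ATTRIBUTES)
    if q_row.shape[-1] != n_t:
        raise ValueError(f"expected {n_t} template attributes, got {q_row.shape[-1]}")
    if r_row.shape[-1] != n_c:
        raise ValueError(f"expected {n_c} clone attributes, got {r_row.shape[-1]}")
    out = (
        mu
        + q_row @ delta[:n_t]
        + np.asarray(eps_template, dtype=float)
        + r_row @ delta[n_t:]
        + np.asarray(eps_clone, dtype=float)
    )
    return out if out.size > 1 else out.item()


def compose_difficulty(coeffs: StructureCoefficients, q_row, r_row,
                       eps_template=0.0, eps_clone=0.0):
    """Additive difficulty: intercept + attribute effects + residuals.

    Exactly linear in every argument; vectorizes over rows of ``q_row`` /
    ``r_row`` with matching residual vectors.
    """
    return _compose(coeffs.mu_beta, coeffs.delta_beta, q_row, r_row, eps_template, eps_clone)


def compose_discrimination(coeffs: StructureCoefficients, q_row, r_row,
                           eps_template=0.0, eps_clone=0.0,
                           bounds=ALPHA_BOUNDS, on_out_of_bounds="raise"):
    """Additive discrimination, validated against the estimation bounds [0, 5].

    ``on_out_of_bounds`` is one of ``"raise"``, ``"clip"`` or ``"ignore"``.
    """
    alpha = _compose(coeffs.mu_alpha, coeffs.delta_alpha, q_row, r_row, eps_template, eps_clone)
    arr = np.atleast_1d(np.asarray(alpha, dtype=float))
    out = (arr < bounds[0]) | (arr > bounds[1])
    if out.any():
        if on_out_of_bounds == "raise":
            raise ValueError(
                f"{int(out.sum())} composed discrimination value(s) outside {bounds}"
            )
        if on_out_of_bounds == "clip":
            arr = np.clip(arr, *bounds)
            alpha = arr if arr.size > 1 else arr.item()
        elif on_out_of_bounds != "ignore":
            raise ValueError(f"unknown on_out_of_bounds={on_out_of_bounds!r}")
    return alpha


def ability_residual_scale(rho) -> float:
    """Standard deviation of the ability residual, ``sqrt(1 - sum(rho**2))``."""
    ssq = float(np.sum(np.asarray(rho, dtype=float) ** 2))
    if ssq >= 1.0:
        raise ValueError(f"sum(rho**2) = {ssq:.3f} >= 1; ability variance not identifiable")
    return float(np.sqrt(1.0 - ssq))


def compose_ability(x_row, rho, eps):
    """Latent ability as covariate effects plus residual: ``theta = X @ rho + eps``.

    In generative use ``eps ~ Normal(0, 1 - sum(rho**2))`` so that the
    marginal variance of ability is (approximately) one.
    """
    ability_residual_scale(rho)  # validates the invariant
    x_row = np.asarray(x_row, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if x_row.shape[-1] != rho.shape[0]:
        raise ValueError("covariate row and rho length mismatch")
    out = x_row @ rho + np.asarray(eps, dtype=float)
    return out if np.ndim(out) else float(out)


def orthogonalize_attribute(values, covariates) -> np.ndarray:
    """Least-squares residualize ``values`` on ``covariates`` plus a constant.

    The returned vector has (numerically) zero inner product with every
    covariate column and with the constant; used to de-collinearize the mean
    log-RT clone attribute from element number, rule number and distractor
    type before it enters the item structure.
    """
    values = np.asarray(values, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != values.shape[0]:
        covariates = covariates.T
    if covariates.shape[0] != values.shape[0]:
        raise ValueError("values and covariates have incompatible shapes")
    design = np.column_stack([np.ones(len(values)), covariates])
    if len(values) < design.shape[1]:
        raise ValueError("need at least as many clones as covariates (plus constant)")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def marginal_attribute_effect(delta: float, mu_beta: float,
                              gamma: float = DEFAULT_GUESSING) -> float:
    """Accuracy change (percentage points) for a one-unit attribute contrast.

    Evaluates the 3PL response probability at average ability (theta = 0) for
    difficulties ``mu_beta -/+ delta/2`` — a symmetric one-unit contrast
    around the average item — and returns 100 times the difference.  Positive
    values mean the attribute makes items harder.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    p_easy = response_probability(0.0, mu_beta - delta / 2.0, 1.0, gamma)
    p_hard = response_probability(0.0, mu_beta + delta / 2.0, 1.0, gamma)
    return float(100.0 * (p_easy - p_hard))
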