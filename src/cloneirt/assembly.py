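"""Test information, reliability, and optimal assembly of parallel forms.

Given calibrated 3PL parameters, a test form's characteristic curve (TCC) is
the sum of item response probabilities and its information function (TIF)
the sum of item Fisher informations.  Optimal assembly selects clones by
mixed integer programming (HiGHS, through :func:`scipy.optimize.milp`):
maximize the minimum TIF over a small ability grid, minus a weighted penalty
on pairwise inter-form TIF gaps (with an optional hard gap tolerance), under
hard constraints — fixed form length, at most one clone per template per
form, optional identical template sets across forms (short-form mode),
optional clone uniqueness across forms, and optional per-form distractor
homogeneity (a form uses minimal-difference or paired-difference clones, not
both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, milp

from .core import DEFAULT_GUESSING, response_probability

__all__ = [
    "TestForm",
    "AssemblyProblem",
    "AssemblyInfeasibleError",
    "item_information",
    "test_curves",
    "reliability",
    "solve_assembly",
    "evaluate_forms",
]

DEFAULT_THETA_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)


class AssemblyInfeasibleError(ValueError):
    """Raised when the assembly constraints cannot all be satisfied."""


def item_information(theta, beta, alpha, gamma=DEFAULT_GUESSING):
    """Fisher information of a 3PL item at ability ``theta``.

    ``I = alpha**2 * ((p - gamma) / (1 - gamma))**2 * (1 - p) / p``; always
    nonnegative, vanishing as ``theta -> +/-inf``.
    """
    p = response_probability(theta, beta, alpha, gamma)
    alpha = np.asarray(alpha, dtype=float)
    return alpha**2 * ((p - gamma) / (1.0 - gamma)) ** 2 * (1.0 - p) / p


def test_curves(params: pd.DataFrame, theta_grid) -> tuple[np.ndarray, np.ndarray]:
    """Test characteristic curve and information function on a grid.

    Both are additive over the items in ``params`` (columns ``beta``,
    ``alpha`` and optionally ``gamma``); an empty item set yields zero
    curves.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if len(params) == 0:
        return np.zeros_like(theta_grid), np.zeros_like(theta_grid)
    beta = params["beta"].to_numpy()[:, None]
    alpha = params["alpha"].to_numpy()[:, None]
    gamma = (params["gamma"].to_numpy()[:, None] if "gamma" in params
             else DEFAULT_GUESSING)
    t = theta_grid[None, :]
    tcc = response_probability(t, beta, alpha, gamma).sum(axis=0)
    tif = item_information(t, beta, alpha, gamma).sum(axis=0)
    return tcc, tif


def reliability(params: pd.DataFrame, n_quad: int = 61) -> float:
    """Marginal IRT reliability of the number-correct score.

    ``rho = Var_theta[TCC] / (Var_theta[TCC] + E_theta[sum p(1-p)])`` with
    ``theta ~ Normal(0, 1)`` integrated by Gauss-Hermite quadrature; lies in
    [0, 1).
    """
    if len(params) == 0:
        raise ValueError("reliability of an empty item set is undefined")
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    beta = params["beta"].to_numpy()[:, None]
    alpha = params["alpha"].to_numpy()[:, None]
    gamma = (params["gamma"].to_numpy()[:, None] if "gamma" in params
             else DEFAULT_GUESSING)
    p = response_probability(nodes[None, :], beta, alpha, gamma)
    tcc = p.sum(axis=0)
    err = (p * (1.0 - p)).sum(axis=0)
    mean_tcc = float(weights @ tcc)
    var_true = float(weights @ (tcc - mean_tcc) ** 2)
    mean_err = float(weights @ err)
    return var_true / (var_true + mean_err)


@dataclass(frozen=True)
class TestForm:
    """A selected clone set with its curves and reliability."""

    clone_ids: tuple
    theta_grid: tuple
    tcc: np.ndarray
    tif: np.ndarray
    reliability: float

    def __len__(self) -> int:
        return len(self.clone_ids)


@dataclass
class AssemblyProblem:
    """Specification of one mixed-integer assembly run.

    ``items`` needs columns ``clone_id``, ``template_id``,
    ``distractor_type``, ``beta``, ``alpha`` (and optionally ``gamma``).
    """

    items: pd.DataFrame
    n_forms: int
    form_length: int
    theta_grid: tuple = DEFAULT_THETA_GRID
    shared_templates: bool = False
    clone_unique_across_forms: bool = True
    distractor_homogeneous: bool = True
    parallelism_tol: float = 0.5
    gap_weight: float = 1.0
    #: branch-and-bound wall clock cap; the incumbent + bound gap is returned
    #: when it is hit (proving optimality exactly can be slow at bank scale)
    time_limit_s: float | None = 60.0
    tie_break_eps: float = 1e-7

    def __post_init__(self) -> None:
        if len(self.theta_grid) == 0:
            raise ValueError("theta grid must be nonempty")
        need = {"clone_id", "template_id", "distractor_type", "beta", "alpha"}
        missing = need - set(self.items.columns)
        if missing:
            raise ValueError(f"items table is missing columns: {sorted(missing)}")


def _precheck(problem: AssemblyProblem) -> None:
    items = problem.items
    n_templates = items["template_id"].nunique()
    if problem.form_length > n_templates:
        raise AssemblyInfeasibleError(
            f"form length {problem.form_length} exceeds the {n_templates} "
            "available templates (at most one clone per template per form)"
        )
    if problem.clone_unique_across_forms:
        if problem.n_forms * problem.form_length > len(items):
            raise AssemblyInfeasibleError(
                f"{problem.n_forms} forms x {problem.form_length} items need more "
                f"clones than the bank holds ({len(items)}) under clone uniqueness"
            )
        if problem.shared_templates:
            per_tpl = items.groupby("template_id").size().max()
            if problem.n_forms > per_tpl:
                raise AssemblyInfeasibleError(
                    "shared templates with clone uniqueness need at least one "
                    f"clone per template per form; max clones/template is {per_tpl}"
                )


def solve_assembly(problem: AssemblyProblem) -> list[TestForm]:
    """Solve the assembly problem to proven optimality (or report the gap).

    Ties among equally optimal selections are broken lexicographically by
    clone id through an epsilon cost, for reproducibility.
    """
    _precheck(problem)
    items = problem.items.sort_values("clone_id").reset_index(drop=True)
    K, F = len(items), problem.n_forms
    grid = np.asarray(problem.theta_grid, dtype=float)
    T = len(grid)
    gamma = (items["gamma"].to_numpy() if "gamma" in items
             else np.full(K, DEFAULT_GUESSING))
    info = np.stack([
        item_information(t, items["beta"].to_numpy(), items["alpha"].to_numpy(), gamma)
        for t in grid
    ])  # (T, K)

    template_ids = items["template_id"].unique()
    J = len(template_ids)
    tpl_pos = {tid: j for j, tid in enumerate(template_ids)}
    tpl_of = items["template_id"].map(tpl_pos).to_numpy()
    is_md = (items["distractor_type"] == "MD").to_numpy()

    pairs = [(f1, f2) for f1 in range(F) for f2 in range(f1 + 1, F)]
    n_x = K * F
    i_y = n_x
    i_gap = i_y + 1
    n_gap = len(pairs) * T
    i_z = i_gap + n_gap
    n_z = J if problem.shared_templates else 0
    i_d = i_z + n_z
    n_d = F if problem.distractor_homogeneous else 0
    n_var = i_d + n_d

    def xi(k, f):
        return k * F + f

    c = np.zeros(n_var)
    c[i_y] = -1.0
    c[i_gap:i_gap + n_gap] = problem.gap_weight
    # lexicographic tie-break: tiny preference for low clone ids
    c[:n_x] += problem.tie_break_eps * np.repeat(np.arange(K), F) / max(K, 1)

    rows, cols, vals = [], [], []
    lo_c, hi_c = [], []
    r = 0

    def add_row(entries, lo, hi):
        nonlocal r
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lo_c.append(lo)
        hi_c.append(hi)
        r += 1

    for f in range(F):  # form length
        add_row([(xi(k, f), 1.0) for k in range(K)],
                problem.form_length, problem.form_length)

    for j in range(J):  # one clone per template per form (shared-template mode
        ks = np.where(tpl_of == j)[0]  # ties usage to a template indicator)
        for f in range(F):
            entries = [(xi(k, f), 1.0) for k in ks]
            if problem.shared_templates:
                add_row(entries + [(i_z + j, -1.0)], 0.0, 0.0)
            else:
                add_row(entries, 0.0, 1.0)

    for f in range(F):  # y <= TIF_f(t)
        for t in range(T):
            add_row([(xi(k, f), info[t, k]) for k in range(K)] + [(i_y, -1.0)],
                    0.0, np.inf)

    for pi, (f1, f2) in enumerate(pairs):  # |TIF_f1 - TIF_f2| <= gap var
        for t in range(T):
            gcol = i_gap + pi * T + t
            ent = [(xi(k, f1), info[t, k]) for k in range(K)]
            ent += [(xi(k, f2), -info[t, k]) for k in range(K)]
            add_row(ent + [(gcol, -1.0)], -np.inf, 0.0)
            ent2 = [(xi(k, f1), -info[t, k]) for k in range(K)]
            ent2 += [(xi(k, f2), info[t, k]) for k in range(K)]
            add_row(ent2 + [(gcol, -1.0)], -np.inf, 0.0)

    if problem.clone_unique_across_forms:
        for k in range(K):
            add_row([(xi(k, f), 1.0) for f in range(F)], 0.0, 1.0)

    if problem.distractor_homogeneous:
        for f in range(F):
            for k in range(K):
                if is_md[k]:
                    add_row([(xi(k, f), 1.0), (i_d + f, -1.0)], -np.inf, 0.0)
                else:
                    add_row([(xi(k, f), 1.0), (i_d + f, 1.0)], -np.inf, 1.0)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    constraint = LinearConstraint(A, np.asarray(lo_c), np.asarray(hi_c))

    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    lb[i_y], ub[i_y] = -np.inf, np.inf
    gap_ub = problem.parallelism_tol if problem.parallelism_tol is not None else np.inf
    lb[i_gap:i_gap + n_gap] = 0.0
    ub[i_gap:i_gap + n_gap] = gap_ub
    integrality = np.ones(n_var)
    integrality[i_y] = 0
    integrality[i_gap:i_gap + n_gap] = 0

    options = {}
    if problem.time_limit_s is not None:
        options["time_limit"] = problem.time_limit_s
    res = milp(c, constraints=constraint, bounds=Bounds(lb, ub),
               integrality=integrality, options=options)
    if res.status == 2 or res.x is None:
        raise AssemblyInfeasibleError(
            "assembly problem is infeasible with the requested form length, "
            "template/clone uniqueness and distractor constraints"
        )
    if res.status == 1:
        mip_gap = getattr(res, "mip_gap", None)
        import logging
        logging.getLogger(__name__).warning(
            "solver hit the time limit; returning incumbent (gap=%s)", mip_gap
        )

    x = res.x[:n_x].reshape(K, F) > 0.5
    forms = []
    for f in range(F):
        sel = items.loc[x[:, f]]
        tcc, tif = test_curves(sel, grid)
        forms.append(TestForm(
            clone_ids=tuple(int(cid) for cid in sel["clone_id"]),
            theta_grid=tuple(grid), tcc=tcc, tif=tif,
            reliability=reliability(sel.assign(gamma=gamma[x[:, f]])),
        ))
    return forms


def evaluate_forms(forms: list[TestForm], items: pd.DataFrame | None = None,
                   n_quad: int = 61) -> pd.DataFrame:
    """Summary report for a set of assembled forms.

    Expected scores are reported both at average ability (theta = 0) and
    averaged over a standard-normal ability population (the two natural
    reading of "expected score"); plus reliability and, with more than one
    form, the maximum pairwise TIF gap per grid point.
    """
    if not forms:
        raise ValueError("no forms to evaluate")
    rows = []
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    for i, form in enumerate(forms):
        if items is not None:
            sel = items.set_index("clone_id").loc[list(form.clone_ids)].reset_index()
            tcc_quad, _ = test_curves(sel, nodes)
            tcc0, _ = test_curves(sel, [0.0])
            exp_pop = float(weights @ tcc_quad)
            exp_mid = float(tcc0[0])
        else:
            exp_pop = np.nan
            gi = list(form.theta_grid)
            exp_mid = float(form.tcc[gi.index(0.0)]) if 0.0 in gi else np.nan
        rows.append({
            "form": i + 1,
            "n_items": len(form),
            "reliability": form.reliability,
            "expected_score_theta0": exp_mid,
            "expected_score_population": exp_pop,
        })
    out = pd.DataFrame(rows)
    if len(forms) > 1:
        tifs = np.stack([f.tif for f in forms])
        out.attrs["max_pairwise_tif_gap"] = float(
            np.max(np.abs(tifs[:, None, :] - tifs[None, :, :]))
        )
    return out
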