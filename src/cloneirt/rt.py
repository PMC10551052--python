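"""Response-time mixed model and person-level RT covariates.

Log response times are modeled with a random-intercepts linear mixed model:
``log(RT) ~ accuracy * score * difficulty + (1 | person)`` where accuracy is
the (centered) trial outcome, score is the person's standardized rest score
(total correct on all other items), and difficulty is the standardized
empirical item difficulty (one minus the proportion correct for the item).
Timeout trials are excluded from the RT model but are retained (coded
incorrect) by the item response models.

The same records also yield the two person-level covariates of the
explanatory ability model: each person's log RTs are regressed on an
intercept and item difficulty; the intercept becomes the mean-RT covariate
and the slope the delta-RT covariate (response-time slowing on harder
items), both standardized across persons.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = ["fit_rt_lmm", "person_rt_covariates"]

_TERMS = [
    ("Intercept", "Intercept"),
    ("accuracy_c", "Accuracy"),
    ("score_z", "Score"),
    ("difficulty_z", "Difficulty"),
    ("accuracy_c:score_z", "Accuracy x Score"),
    ("accuracy_c:difficulty_z", "Accuracy x Difficulty"),
    ("score_z:difficulty_z", "Score x Difficulty"),
    ("accuracy_c:score_z:difficulty_z", "Accuracy x Score x Difficulty"),
]


def _prepare_rt_frame(records: pd.DataFrame) -> pd.DataFrame:
    valid = records.loc[~records["timeout"]].copy()
    if (valid["rt"] <= 0).any():
        raise ValueError("response times must be positive")
    total = records.groupby("person_id")["accuracy"].transform("sum")
    records = records.assign(_rest=total - records["accuracy"])
    valid = records.loc[~records["timeout"]].copy()

    diff_by_clone = 1.0 - records.groupby("clone_id")["accuracy"].mean()
    valid["difficulty"] = valid["clone_id"].map(diff_by_clone)

    for raw, out in (("accuracy", "accuracy_c"), ("_rest", "score_z"), ("difficulty", "difficulty_z")):
        x = valid[raw].astype(float)
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"predictor {raw!r} has zero variance")
        if raw == "accuracy":
            valid[out] = x - x.mean()          # centered, not rescaled
        else:
            valid[out] = (x - x.mean()) / sd
    valid["log_rt"] = np.log(valid["rt"].astype(float))
    return valid


def fit_rt_lmm(records: pd.DataFrame) -> pd.DataFrame:
    """REML fit of the log-RT mixed model; returns the coefficient table.

    Columns: term, coef, se, z, p, ci_low, ci_high — one row per fixed
    effect in the accuracy x score x difficulty factorial layout.
    """
    frame = _prepare_rt_frame(records)
    if frame["person_id"].nunique() < 2:
        raise ValueError("random-intercept variance needs at least two persons")
    model = smf.mixedlm(
        "log_rt ~ accuracy_c * score_z * difficulty_z",
        data=frame, groups=frame["person_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    rows = []
    for key, label in _TERMS:
        rows.append({
            "term": label,
            "coef": fit.params[key],
            "se": fit.bse[key],
            "z": fit.tvalues[key],
            "p": fit.pvalues[key],
            "ci_low": fit.params[key] - 1.96 * fit.bse[key],
            "ci_high": fit.params[key] + 1.96 * fit.bse[key],
        })
    table = pd.DataFrame(rows)
    table.attrs["person_intercept_var"] = float(fit.cov_re.iloc[0, 0])
    table.attrs["residual_var"] = float(fit.scale)
    return table


def person_rt_covariates(records: pd.DataFrame,
                         difficulty_by_clone: pd.Series | None = None,
                         min_valid: int = 3) -> pd.DataFrame:
    """Per-person mean-RT and delta-RT covariates from log-RT regressions.

    Each person's log RTs (timeouts excluded) are regressed on an intercept
    and centered item difficulty (one minus the sample proportion correct for
    the item unless supplied); the intercept and slope are then standardized
    across persons.  Persons with fewer than ``min_valid`` valid RTs are
    flagged and imputed at the mean (0 after standardization) with a warning.
    """
    if difficulty_by_clone is None:
        difficulty_by_clone = 1.0 - records.groupby("clone_id")["accuracy"].mean()
    valid = records.loc[~records["timeout"]].copy()
    valid["difficulty"] = valid["clone_id"].map(difficulty_by_clone)
    valid["difficulty"] -= valid["difficulty"].mean()
    valid["log_rt"] = np.log(valid["rt"].astype(float))

    person_ids = np.sort(records["person_id"].unique())
    rows = []
    for pid in person_ids:
        sub = valid[valid["person_id"] == pid]
        if len(sub) < min_valid:
            rows.append((pid, np.nan, np.nan, True))
            continue
        x = sub["difficulty"].to_numpy()
        design = np.column_stack([np.ones(len(sub)), x])
        coef, *_ = np.linalg.lstsq(design, sub["log_rt"].to_numpy(), rcond=None)
        slope = coef[1] if np.ptp(x) > 0 else 0.0
        rows.append((pid, coef[0], slope, False))
    out = pd.DataFrame(rows, columns=["person_id", "mean_rt", "delta_rt", "flagged"])
    if out["flagged"].any():
        warnings.warn(
            f"{int(out['flagged'].sum())} person(s) had fewer than {min_valid} "
            "valid response times; covariates imputed at 0"
        )
    for col, zcol in (("mean_rt", "mean_rt_z"), ("delta_rt", "delta_rt_z")):
        x = out[col]
        sd = x.std()
        out[zcol] = ((x - x.mean()) / sd if sd and np.isfinite(sd) else 0.0)
        out[zcol] = out[zcol].fillna(0.0)
    return out
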