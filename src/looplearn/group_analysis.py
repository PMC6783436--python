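"""Group-level statistics on fitted learning parameters.

Covers the downstream analyses run on the per-subject posterior-mean
parameters: the Valence Bias Score, repeated-measures ANOVAs (with an
optional between-subjects factor), Pearson/partial correlations with
trait scores, the Fisher z comparison of two independent correlations,
and posterior predictive checks (per-subject R^2 of predicted vs observed
ratings plus a re-run of the model-free trial ANOVA on the predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .learning_models import ModelSpec, predict_trajectory

__all__ = [
    "valence_bias_score",
    "valence_bias_table",
    "learning_rate_table",
    "rm_anova",
    "partial_corr",
    "fisher_z_compare",
    "ppc",
    "model_free_anova",
    "PpcReport",
]


# ---------------------------------------------------------------------------
# valence bias
# ---------------------------------------------------------------------------

def valence_bias_score(alpha_pos: float, alpha_neg: float) -> float:
    """Normalized learning-rate asymmetry
    (alpha_pos - alpha_neg) / (alpha_pos + alpha_neg).

    Positive values indicate a positivity bias (greater updating after
    better-than-expected feedback), negative values a negativity bias.
    The score is invariant to a common rescaling of both rates and is
    undefined (NaN, with a warning) when both rates are zero.
    """
    if alpha_pos < 0 or alpha_neg < 0:
        raise ValueError("learning rates must be non-negative")
    denom = alpha_pos + alpha_neg
    if denom == 0:
        warnings.warn("valence bias undefined: both learning rates are zero")
        return float("nan")
    return (alpha_pos - alpha_neg) / denom


def learning_rate_table(
    fits: dict[str, dict[str, object]], model_name: str, stat: str = "mean"
) -> pd.DataFrame:
    """Per-subject posterior central tendencies of all parameters of one
    model, one row per subject."""
    rows = []
    for sid, per_model in fits.items():
        fit = per_model[model_name]
        vals = fit.posterior_mean if stat == "mean" else fit.posterior_median
        rows.append({"subject_id": sid, **vals})
    return pd.DataFrame(rows)


def valence_bias_table(
    rates: pd.DataFrame,
    pos_col: str = "alpha_pos_self",
    neg_col: str = "alpha_neg_self",
) -> pd.Series:
    """Valence Bias Score per subject from a learning-rate table."""
    denom = rates[pos_col] + rates[neg_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (rates[pos_col] - rates[neg_col]) / denom
    score = score.where(denom != 0)
    if score.isna().any():
        warnings.warn(
            f"{int(score.isna().sum())} subject(s) with undefined bias score "
            "(both learning rates zero); excluded listwise downstream"
        )
    score.index = rates["subject_id"] if "subject_id" in rates else rates.index
    return score.rename("valence_bias")


# ---------------------------------------------------------------------------
# repeated-measures / split-plot ANOVA
# ---------------------------------------------------------------------------

def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Univariate repeated-measures ANOVA on a balanced long-format table.

    Supports any number of fully-crossed within-subject factors and one
    optional between-subjects factor (split-plot design).  The subject is
    treated as a random blocking factor: each within-effect F uses its own
    effect-by-subject interaction as the error term, and the between
    effect uses subjects-within-groups.  Replicate observations per
    (subject x within-cell) are averaged first.  Sums of squares are
    computed by Yates' method of weighted cell means, which for balanced
    data coincides with Type III.
    """
    if isinstance(within, str):
        within = [within]
    if not within:
        raise ValueError("need at least one within-subject factor")
    cols = [subject, dv] + within + ([between] if between else [])
    df = data[cols].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable")

    if between:
        groups = df.groupby(subject)[between].nunique()
        if (groups != 1).any():
            raise ValueError("each subject must belong to a single group")

    # collapse replicates, check balance
    key = [subject] + within + ([between] if between else [])
    df = df.groupby(key, as_index=False, observed=True)[dv].mean()
    counts = df.groupby(subject, observed=True)[dv].size()
    n_cells = int(np.prod([df[w].nunique() for w in within]))
    if (counts != n_cells).any():
        raise ValueError("design not balanced: missing within-cells detected")

    n_subj = df[subject].nunique()
    n_grp = df[between].nunique() if between else 1
    if between and n_subj - n_grp < 1:
        raise ValueError("need >= 2 subjects per between group")

    y = df[dv].to_numpy(float)
    grand = y.mean()

    def cellmean(cs):
        if not cs:
            return np.full(len(df), grand)
        return df.groupby(cs, observed=True)[dv].transform("mean").to_numpy()

    # effects are (within-subset, unit) with unit in {"", "G", "S"}
    # ("G" = between groups, "S" = subjects; S is nested in G)
    unit_rank = {"": 0, "G": 1, "S": 2}
    w_subsets = [()] + [
        c for r in range(1, len(within) + 1) for c in combinations(within, r)
    ]
    effects = []
    for ws in w_subsets:
        for unit in ("", "G", "S"):
            if unit == "G" and not between:
                continue
            if ws == () and unit == "":
                continue
            effects.append((ws, unit))

    terms: dict[tuple, np.ndarray] = {((), ""): np.full(len(df), grand)}
    ss: dict[tuple, float] = {}
    dfs: dict[tuple, float] = {}
    for ws, unit in effects:
        cs = list(ws)
        if unit == "G":
            cs += [between]
        elif unit == "S":
            cs += [subject]
        m = cellmean(cs)
        resid = m.copy()
        for (ws2, unit2), t in terms.items():
            if set(ws2) <= set(ws) and unit_rank[unit2] <= unit_rank[unit] and (
                ws2, unit2
            ) != (ws, unit):
                resid = resid - t
        terms[(ws, unit)] = resid
        ss[(ws, unit)] = float(resid @ resid)
        d = float(np.prod([df[w].nunique() - 1 for w in ws])) if ws else 1.0
        if unit == "G":
            d *= n_grp - 1
        elif unit == "S":
            d *= n_subj - n_grp if between else (n_subj - 1 if ws else n_subj - 1)
        dfs[(ws, unit)] = d
    if between:
        dfs[((), "S")] = float(n_subj - n_grp)

    def label(ws, unit):
        parts = list(ws) + ([between] if unit == "G" else [])
        return " x ".join(parts) if parts else "(intercept)"

    rows = []
    tested = []
    if between:
        tested.append((((), "G"), ((), "S")))
    for ws in w_subsets[1:]:
        tested.append(((ws, ""), (ws, "S")))
        if between:
            tested.append(((ws, "G"), (ws, "S")))
    for eff, err in tested:
        ss_e, df_e = ss[eff], dfs[eff]
        ss_r, df_r = ss[err], dfs[err]
        ms_e = ss_e / df_e if df_e > 0 else np.nan
        ms_r = ss_r / df_r if df_r > 0 else np.nan
        if ss_e < 1e-12:
            f, p = 0.0, 1.0
        elif not np.isfinite(ms_r) or ms_r <= 0:
            f, p = np.nan, np.nan
        else:
            f = ms_e / ms_r
            p = float(stats.f.sf(f, df_e, df_r))
        rows.append(
            {
                "effect": label(*eff),
                "ss": ss_e,
                "df1": df_e,
                "df2": df_r,
                "F": f,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def partial_corr(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given control variables.

    Equals the Pearson correlation of the residuals of x and y after
    linear removal of the controls; with no controls it reduces to the
    plain Pearson r.  Degenerate cases (y explained exactly by the
    controls) return r = 0 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    if controls is None or (np.size(controls) == 0):
        x, y = x[keep], y[keep]
        if len(x) < 3:
            raise ValueError("need at least 3 complete observations")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    c = np.asarray(controls, float)
    if c.ndim == 1:
        c = c[:, None]
    keep &= np.isfinite(c).all(axis=1)
    x, y, c = x[keep], y[keep], c[keep]
    n, k = c.shape
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("controls are rank deficient")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(ry, 0) or np.allclose(rx, 0):
        warnings.warn("degenerate partial correlation: variable fully "
                      "explained by controls")
        return 0.0, 1.0
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    # t test with dof = n - k - 2
    dof = n - k - 2
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), dof))
    return r, p


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("each sample needs n >= 4")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def _prediction_frame(fits, datasets, model: ModelSpec, stat: str = "mean"):
    rows = []
    for data in datasets:
        fit = fits[data.subject_id][model.name]
        params = fit.to_parameter_set(model, stat=stat)
        traj = predict_trajectory(model, params, data.design, data=data)
        df = data.design.to_frame()
        df.insert(0, "subject_id", data.subject_id)
        df["observed"] = data.exp_ratings
        df["predicted"] = traj.latent_exp
        df["cond_trial"] = df.groupby(["agent", "ability"]).cumcount() + 1
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@dataclass
class PpcReport:
    """Posterior predictive check summary.

    ``per_subject`` holds one R^2 row per subject x condition plus an
    "overall" row; ``anova_predicted`` re-runs the model-free trial ANOVA
    on the model predictions.
    """

    per_subject: pd.DataFrame
    anova_predicted: pd.DataFrame
    predictions: pd.DataFrame

    @property
    def overall_r2(self) -> pd.Series:
        sub = self.per_subject[self.per_subject["condition"] == "overall"]
        return sub.set_index("subject_id")["r2"]


def _r2(obs, pred):
    if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
        warnings.warn("degenerate R^2: constant predictions or observations")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def ppc(fits, datasets, model: ModelSpec, stat: str = "mean") -> PpcReport:
    """Posterior predictive check for one model across a cohort.

    Per subject, the R^2 between the trajectory predicted at the posterior
    central tendency and the observed ratings is computed within each
    (agent x ability) condition and overall; the model-free
    trial-by-condition ANOVA is then repeated on the predicted data.
    """
    pred = _prediction_frame(fits, datasets, model, stat=stat)
    rows = []
    for sid, sub in pred.groupby("subject_id", sort=False):
        for (agent, ability), cell in sub.groupby(["agent", "ability"]):
            rows.append(
                {
                    "subject_id": sid,
                    "condition": f"{agent}_{ability}",
                    "r2": _r2(cell["observed"], cell["predicted"]),
                }
            )
        rows.append(
            {
                "subject_id": sid,
                "condition": "overall",
                "r2": _r2(sub["observed"], sub["predicted"]),
            }
        )
    anova = model_free_anova(pred, dv="predicted")
    return PpcReport(
        per_subject=pd.DataFrame(rows), anova_predicted=anova, predictions=pred
    )


def model_free_anova(trials: pd.DataFrame, dv: str = "observed") -> pd.DataFrame:
    """Trial x Ability (x Agent) repeated-measures ANOVA on a long trial
    table with columns subject_id, agent, ability, cond_trial and ``dv``."""
    within = ["cond_trial", "ability"]
    if trials["agent"].nunique() > 1:
        within.append("agent")
    return rm_anova(trials, dv=dv, within=within, subject="subject_id")
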