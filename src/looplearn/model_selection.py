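"""Model comparison: PSIS-LOO per subject and group-level random-effects
Bayesian model selection.

Per subject, approximate leave-one-trial-out cross-validation is computed
from the posterior pointwise log-likelihoods by Pareto-smoothed importance
sampling (PSIS); the per-trial Pareto shape estimate k-hat diagnoses the
reliability of each importance estimate (flag above 0.7).  Per-subject sum
PSIS-LOO scores in natural-log units then enter a random-effects
group-level comparison: a Dirichlet prior over population model
frequencies is updated by fixed-point variational iteration, exceedance
probabilities are estimated by Monte-Carlo over the Dirichlet posterior,
and the Bayesian omnibus risk (BOR) -- the posterior probability that all
model frequencies are equal -- shrinks the exceedance probabilities toward
uniform (protected exceedance probability, pxp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, softmax

__all__ = [
    "LooResult",
    "BmsResult",
    "psis_loo",
    "loo_from_fit",
    "loo_table",
    "loo_sensitivity",
    "loo_diff",
    "evidence_matrix",
    "bms",
]

KHAT_THRESHOLD = 0.7


@dataclass
class LooResult:
    """PSIS-LOO decomposition for one subject under one model."""

    subject_id: str
    model_name: str
    elpd_loo: float
    pointwise_elpd: np.ndarray
    loo_se: float
    khat: np.ndarray
    flagged_trials: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.pointwise_elpd)


def psis_loo(
    pointwise_loglik: np.ndarray,
    subject_id: str = "",
    model_name: str = "",
    khat_threshold: float = KHAT_THRESHOLD,
) -> LooResult:
    """PSIS-LOO from a (draws, trials) pointwise log-likelihood array.

    Per trial the importance ratios are 1/p(y_t | theta_s); the largest
    min(0.2 S, 3 sqrt(S)) ratios are replaced by fitted generalized-Pareto
    quantiles (Pareto smoothing), the fitted shape is recorded as k-hat,
    and the LOO expected log predictive density for the trial is the log
    of the smoothed-weighted average of the likelihood over draws.  The
    standard error is sqrt(n * var(pointwise elpd)).
    """
    import arviz as az

    ll = np.asarray(pointwise_loglik, float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be (draws, trials)")
    if not np.all(np.isfinite(ll)):
        bad = np.nonzero(~np.isfinite(ll).all(axis=0))[0]
        raise ValueError(f"non-finite log-likelihood at trials {bad.tolist()}")
    n_draws, n_trials = ll.shape
    if n_draws < 100:
        raise ValueError("PSIS-LOO needs at least 100 posterior draws")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, khat = az.psislw(-ll.T)  # (trials, draws), normalized log weights
    lw = np.asarray(lw)
    khat = np.asarray(khat, float)
    # a point posterior gives exactly uniform weights: importance sampling
    # is exact and there is no tail to fit, so mark k-hat as -inf
    degenerate = np.ptp(ll, axis=0) < 1e-12
    khat[degenerate] = -np.inf
    pointwise = logsumexp(lw + ll.T, axis=1)
    se = float(np.sqrt(n_trials * np.var(pointwise, ddof=0)))
    flagged = np.nonzero(khat > khat_threshold)[0]
    return LooResult(
        subject_id=subject_id,
        model_name=model_name,
        elpd_loo=float(pointwise.sum()),
        pointwise_elpd=pointwise,
        loo_se=se,
        khat=khat,
        flagged_trials=flagged,
    )


def loo_from_fit(fit) -> LooResult:
    """PSIS-LOO for a :class:`~looplearn.inference.PosteriorFit`."""
    return psis_loo(fit.pointwise_loglik, fit.subject_id, fit.model_name)


def loo_table(fits: dict[str, dict[str, object]]) -> dict[str, dict[str, LooResult]]:
    """PSIS-LOO for every subject x model fit; loos[subject][model]."""
    return {
        sid: {m: loo_from_fit(f) for m, f in per_model.items()}
        for sid, per_model in fits.items()
    }


def evidence_matrix(
    loos: dict[str, dict[str, LooResult]],
    model_names: list[str] | None = None,
    drop_flagged: bool = False,
) -> pd.DataFrame:
    """Subjects x models matrix of sum PSIS-LOO scores (log-evidence proxies).

    With ``drop_flagged`` the pointwise contributions of trials whose k-hat
    exceeds the threshold under *any* model are removed for that subject in
    every model, keeping the scores comparable across models.
    """
    subjects = list(loos)
    if model_names is None:
        model_names = list(loos[subjects[0]])
    rows = np.empty((len(subjects), len(model_names)))
    for i, sid in enumerate(subjects):
        drop: set[int] = set()
        if drop_flagged:
            for m in model_names:
                drop.update(loos[sid][m].flagged_trials.tolist())
        for j, m in enumerate(model_names):
            res = loos[sid][m]
            if drop:
                keep = np.setdiff1d(np.arange(res.n_trials), list(drop))
                rows[i, j] = res.pointwise_elpd[keep].sum()
            else:
                rows[i, j] = res.elpd_loo
    return pd.DataFrame(rows, index=subjects, columns=model_names)


def loo_sensitivity(
    loos: dict[str, dict[str, LooResult]],
    model_names: list[str] | None = None,
) -> pd.DataFrame:
    """Evidence matrix with unreliable (k-hat flagged) trials excluded,
    for re-running the group-level selection as a sensitivity check."""
    return evidence_matrix(loos, model_names, drop_flagged=True)


def loo_diff(
    loos_a: dict[str, LooResult] | list[LooResult],
    loos_b: dict[str, LooResult] | list[LooResult],
) -> tuple[float, float]:
    """Paired difference in expected predictive accuracy between two models.

    Sums the per-trial elpd differences over all subjects' trials; the SE
    comes from the variance of the paired pointwise differences, the
    convention used for LOO-Diff (SE-Diff) comparisons against the winning
    model.
    """
    if isinstance(loos_a, dict):
        keys = list(loos_a)
        if set(keys) != set(loos_b):
            raise ValueError("the two LOO sets cover different subjects")
        pairs = [(loos_a[k], loos_b[k]) for k in keys]
    else:
        if len(loos_a) != len(loos_b):
            raise ValueError("the two LOO sets cover different subjects")
        pairs = list(zip(loos_a, loos_b))
    diffs = []
    for ra, rb in pairs:
        if ra.n_trials != rb.n_trials:
            raise ValueError(
                f"trial sets differ for subject {ra.subject_id!r}"
            )
        diffs.append(ra.pointwise_elpd - rb.pointwise_elpd)
    d = np.concatenate(diffs)
    return float(d.sum()), float(np.sqrt(len(d) * np.var(d, ddof=0)))


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BmsResult:
    """Group-level random-effects model comparison summary."""

    model_names: list[str]
    alpha: np.ndarray                  # Dirichlet posterior over frequencies
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    protected_exceedance_prob: np.ndarray
    bor: float
    free_energy_rfx: float
    free_energy_null: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected_freq": self.expected_frequencies,
                "xp": self.exceedance_prob,
                "pxp": self.protected_exceedance_prob,
            },
            index=self.model_names,
        )


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(a0_sum)
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))).sum()
    )


def bms(
    evidence: pd.DataFrame | np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BmsResult:
    """Random-effects Bayesian model selection on per-subject log evidence.

    A Dirichlet(1, ..., 1) prior over population model frequencies is
    updated by fixed-point variational iteration; exceedance probabilities
    come from Monte-Carlo draws of the Dirichlet posterior; BOR compares
    the free energy of the random-effects model against the null of equal
    frequencies, and pxp = (1 - BOR) * xp + BOR / K.
    """
    if isinstance(evidence, pd.DataFrame):
        names = list(evidence.columns)
        lme = evidence.to_numpy(float)
    else:
        lme = np.asarray(evidence, float)
        names = [f"model_{j}" for j in range(lme.shape[1])]
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be (subjects, >=2 models)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence contains non-finite values")
    n, K = lme.shape
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        u = softmax(logu, axis=1)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    logu = lme + digamma(alpha) - digamma(alpha.sum())
    u = softmax(logu, axis=1)

    # variational free energy of the random-effects model
    f_rfx = float(
        (u * lme).sum()
        + (u * (digamma(alpha) - digamma(alpha.sum()))).sum()
        - (u * np.log(u + 1e-300)).sum()
        - _dirichlet_kl(alpha, alpha0)
    )
    # null model: all frequencies equal (each subject mixes models 1/K)
    f_null = float(logsumexp(lme, axis=1).sum() - n * np.log(K))
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples
    pxp = (1.0 - bor) * xp + bor / K
    return BmsResult(
        model_names=names,
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_prob=xp,
        protected_exceedance_prob=pxp,
        bor=bor,
        free_energy_rfx=f_rfx,
        free_energy_null=f_null,
    )
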