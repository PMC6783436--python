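"""Per-subject Bayesian fitting of the learning models by MCMC.

Each subject x model pair is fitted independently (no hierarchical
pooling).  The default backend is a self-contained componentwise
random-walk Metropolis sampler with scale adaptation during warmup,
operating on an unconstrained reparameterization (logit for learning
rates and rating-scale values, log for the noise SD).  Any backend
honouring the ``backend(model, data, cfg) -> (draws, pointwise_loglik)``
contract can be plugged in instead.

Priors (the likelihood alone identifies the parameters well at the task's
trial counts, so these are weakly informative and scale-appropriate):

* learning rates: uniform on [0, 1]
* initial expectations / condition means: normal(50, 20) truncated to [0, 100]
* observation noise SD: half-normal(scale 20)

Convergence is summarised by rank-normalized split R-hat and effective
sample size per parameter; subjects with any R-hat above 1.1 in any
fitted model are flagged for exclusion.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .learning_models import ModelSpec, ParameterSet, njit
from .synthetic_data import BehavioralDataset

__all__ = [
    "SamplerConfig",
    "PosteriorFit",
    "fit_subject",
    "fit_cohort",
    "compute_rhat",
    "compute_ess",
    "apply_exclusions",
    "flag_implausible_parameters",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; defaults are 3 chains, 1000 warmup iterations and
    2400 retained draws in total after thinning by 3."""

    n_chains: int = 3
    n_warmup: int = 1000
    n_retained: int = 2400     # total across chains, after thinning
    thin: int = 3
    seed: int = 0
    prior_init_mean: float = 50.0
    prior_init_sd: float = 20.0
    prior_sigma_scale: float = 20.0

    @property
    def draws_per_chain(self) -> int:
        return self.n_retained // self.n_chains

    @classmethod
    def quick(cls, seed: int = 0) -> "SamplerConfig":
        """Reduced settings for simulation studies (2 chains, 400 warmup,
        600 retained draws, no thinning)."""
        return cls(n_chains=2, n_warmup=400, n_retained=600, thin=1, seed=seed)


# ---------------------------------------------------------------------------
# log posterior and sampler kernels (unconstrained space)
# ---------------------------------------------------------------------------
#
# theta layout: [logit(alpha_1..n_a), logit(v_1..n_v / 100), log(sigma)]
# where v are initial expectations (learning models) or condition means
# (Mean model).  The log posterior includes the log-Jacobian of the
# transform so that the stated priors hold on the constrained scale.

@njit(cache=True)
def _logpost(theta, cond_idx, fb, ratings, slot_map, init_idx, fixed_inits,
             n_a, n_v, is_mean, pi_mean, pi_sd, sig_scale):
    lp = 0.0
    alphas = np.empty(n_a)
    for j in range(n_a):
        a = 1.0 / (1.0 + math.exp(-theta[j]))
        alphas[j] = a
        lp += math.log(a * (1.0 - a) + 1e-300)
    vals = np.empty(n_v)
    for j in range(n_v):
        v = 100.0 / (1.0 + math.exp(-theta[n_a + j]))
        vals[j] = v
        z = (v - pi_mean) / pi_sd
        lp += -0.5 * z * z + math.log(v * (100.0 - v) / 100.0 + 1e-300)
    lsig = theta[n_a + n_v]
    if lsig < -7.0 or lsig > 7.0:
        return -np.inf
    sigma = math.exp(lsig)
    z = sigma / sig_scale
    lp += -0.5 * z * z + lsig

    n_cond = init_idx.shape[0]
    state = np.empty(n_cond)
    for c in range(n_cond):
        if is_mean:
            state[c] = vals[c]
        elif n_v > 0:
            state[c] = vals[init_idx[c]]
        else:
            state[c] = fixed_inits[c]

    n = cond_idx.shape[0]
    cst = -lsig - 0.5 * math.log(2.0 * math.pi)
    inv2 = 0.5 / (sigma * sigma)
    for t in range(n):
        c = cond_idx[t]
        e = state[c]
        r = ratings[t] - e
        lp += cst - r * r * inv2
        if not is_mean:
            pe = fb[t] - e
            s = 0 if pe >= 0.0 else 1
            state[c] = e + alphas[slot_map[c, s]] * pe
    return lp


@njit(cache=True)
def _run_chain(seed, theta0, step0, n_warmup, n_post, thin,
               cond_idx, fb, ratings, slot_map, init_idx, fixed_inits,
               n_a, n_v, is_mean, pi_mean, pi_sd, sig_scale):
    np.random.seed(seed)
    n_par = theta0.shape[0]
    theta = theta0.copy()
    step = step0.copy()
    lp = _logpost(theta, cond_idx, fb, ratings, slot_map, init_idx,
                  fixed_inits, n_a, n_v, is_mean, pi_mean, pi_sd, sig_scale)
    n_keep = n_post // thin
    draws = np.empty((n_keep, n_par))
    acc = np.zeros(n_par)
    n_acc_total = 0.0
    kept = 0
    for it in range(n_warmup + n_post):
        for j in range(n_par):
            old = theta[j]
            theta[j] = old + step[j] * np.random.normal()
            lp_new = _logpost(theta, cond_idx, fb, ratings, slot_map,
                              init_idx, fixed_inits, n_a, n_v, is_mean,
                              pi_mean, pi_sd, sig_scale)
            if math.log(np.random.random() + 1e-300) < lp_new - lp:
                lp = lp_new
                acc[j] += 1.0
                if it >= n_warmup:
                    n_acc_total += 1.0
            else:
                theta[j] = old
        if it < n_warmup and (it + 1) % 50 == 0:
            for j in range(n_par):
                rate = acc[j] / 50.0
                step[j] *= math.exp(1.5 * (rate - 0.44))
                if step[j] < 1e-3:
                    step[j] = 1e-3
                elif step[j] > 10.0:
                    step[j] = 10.0
                acc[j] = 0.0
        if it >= n_warmup and (it - n_warmup + 1) % thin == 0:
            for j in range(n_par):
                draws[kept, j] = theta[j]
            kept += 1
    accept_rate = n_acc_total / (n_post * n_par)
    return draws, accept_rate


@njit(cache=True)
def _constrain_and_pointwise(draws, cond_idx, fb, ratings, slot_map, init_idx,
                             fixed_inits, n_a, n_v, is_mean):
    n_draws, n_par = draws.shape
    n = cond_idx.shape[0]
    n_cond = init_idx.shape[0]
    cdraws = np.empty((n_draws, n_par))
    pointwise = np.empty((n_draws, n))
    state = np.empty(n_cond)
    for d in range(n_draws):
        for j in range(n_a):
            cdraws[d, j] = 1.0 / (1.0 + math.exp(-draws[d, j]))
        for j in range(n_v):
            cdraws[d, n_a + j] = 100.0 / (1.0 + math.exp(-draws[d, n_a + j]))
        sigma = math.exp(draws[d, n_a + n_v])
        cdraws[d, n_a + n_v] = sigma
        for c in range(n_cond):
            if is_mean:
                state[c] = cdraws[d, c]
            elif n_v > 0:
                state[c] = cdraws[d, n_a + init_idx[c]]
            else:
                state[c] = fixed_inits[c]
        cst = -math.log(sigma) - 0.5 * math.log(2.0 * math.pi)
        inv2 = 0.5 / (sigma * sigma)
        for t in range(n):
            c = cond_idx[t]
            e = state[c]
            r = ratings[t] - e
            pointwise[d, t] = cst - r * r * inv2
            if not is_mean:
                pe = fb[t] - e
                s = 0 if pe >= 0.0 else 1
                state[c] = e + cdraws[d, slot_map[c, s]] * pe
    return cdraws, pointwise


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for a (chain, draw) array.

    Returns NaN (flagged as non-convergent downstream) for degenerate
    zero-variance chains, for which R-hat is undefined.
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("R-hat needs a (chain, draw) array with >= 2 chains")
    if draws.shape[1] < 2:
        raise ValueError("R-hat needs >= 2 draws per chain")
    if np.allclose(draws, draws.flat[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws))


def compute_ess(draws: np.ndarray) -> float:
    """Bulk effective sample size for a (chain, draw) array; 0 for a
    degenerate constant chain."""
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 1:
        raise ValueError("ESS needs a (chain, draw) array")
    if draws.shape[1] < 2:
        raise ValueError("ESS needs >= 2 draws per chain")
    if np.allclose(draws, draws.flat[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one subject under one model."""

    subject_id: str
    model_name: str
    param_names: list[str]
    draws: np.ndarray              # (chain, draw, param), constrained scale
    pointwise_loglik: np.ndarray   # (chain*draw, trial)
    rhat: dict[str, float]
    ess: dict[str, float]
    accept_rate: float

    @property
    def posterior_mean(self) -> dict[str, float]:
        m = self.draws.reshape(-1, self.draws.shape[-1]).mean(axis=0)
        return dict(zip(self.param_names, m))

    @property
    def posterior_median(self) -> dict[str, float]:
        m = np.median(self.draws.reshape(-1, self.draws.shape[-1]), axis=0)
        return dict(zip(self.param_names, m))

    @property
    def max_rhat(self) -> float:
        vals = np.asarray(list(self.rhat.values()))
        return float("nan") if np.isnan(vals).any() else float(vals.max())

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "median": np.median(flat, axis=0),
                "rhat": [self.rhat[p] for p in self.param_names],
                "ess": [self.ess[p] for p in self.param_names],
            },
            index=self.param_names,
        )

    def to_parameter_set(self, model: ModelSpec, stat: str = "mean") -> ParameterSet:
        """Central-tendency ParameterSet (posterior mean by default)."""
        vals = self.posterior_mean if stat == "mean" else self.posterior_median
        arr = np.asarray([vals[p] for p in self.param_names])
        n_a = model.n_alpha_slots
        if model.is_mean:
            return ParameterSet(
                alphas=np.empty(0),
                condition_means=arr[: model.n_conditions],
                noise_sd=arr[-1],
            )
        return ParameterSet(
            alphas=arr[:n_a], init_values=arr[n_a:-1], noise_sd=arr[-1]
        )


def _model_arrays(model: ModelSpec, data: BehavioralDataset):
    cond_idx = np.asarray(data.design.cond_idx, dtype=np.int64)
    fb = np.asarray(data.design.feedback, dtype=float)
    ratings = np.asarray(data.exp_ratings, dtype=float)
    n_cond = model.n_conditions
    if model.is_mean:
        slot_map = np.empty((0, 2), dtype=np.int64)
        init_idx = np.arange(n_cond, dtype=np.int64)
        n_a, n_v = 0, n_cond
        fixed = np.zeros(n_cond)
    else:
        slot_map = model.slot_map_array()
        n_a = model.n_alpha_slots
        n_v = model.n_init_params
        if n_v > 0:
            init_idx = model.init_index()
            fixed = np.zeros(n_cond)
        else:  # fixed_first_rating: anchor on the first observed rating
            init_idx = np.arange(n_cond, dtype=np.int64)
            fixed = np.empty(n_cond)
            for c in range(n_cond):
                idx = np.nonzero(cond_idx == c)[0]
                fixed[c] = ratings[idx[0]]
    return cond_idx, fb, ratings, slot_map, init_idx, fixed, n_a, n_v


def _fit_seed(cfg_seed: int, subject_id: str, model_name: str) -> int:
    h = zlib.crc32(f"{subject_id}|{model_name}".encode())
    return int((cfg_seed * 2654435761 + h) % (2**31 - 1))


def _metropolis_backend(model: ModelSpec, data: BehavioralDataset,
                        cfg: SamplerConfig):
    cond_idx, fb, ratings, slot_map, init_idx, fixed, n_a, n_v = _model_arrays(
        model, data
    )
    n_par = n_a + n_v + 1
    n_keep = cfg.draws_per_chain
    n_post = n_keep * cfg.thin
    base = _fit_seed(cfg.seed, data.subject_id, model.name)
    ss = np.random.SeedSequence(base)
    init_rng = np.random.default_rng(ss)
    chain_seeds = ss.generate_state(cfg.n_chains, dtype=np.uint32)

    all_draws = np.empty((cfg.n_chains, n_keep, n_par))
    all_pw = np.empty((cfg.n_chains, n_keep, len(ratings)))
    acc = 0.0
    for ch in range(cfg.n_chains):
        # overdispersed start: alphas from the prior, value parameters near
        # the observed per-condition means, sigma in a moderate band
        theta0 = np.empty(n_par)
        theta0[:n_a] = np.log(u := init_rng.uniform(0.05, 0.95, n_a)) - np.log1p(-u)
        for j in range(n_v):
            v = np.clip(init_rng.normal(50.0, 15.0), 2.0, 98.0)
            theta0[n_a + j] = math.log(v / (100.0 - v))
        theta0[-1] = math.log(init_rng.uniform(5.0, 20.0))
        step0 = np.full(n_par, 0.3)
        draws, a = _run_chain(
            int(chain_seeds[ch]) % (2**31 - 1), theta0, step0,
            cfg.n_warmup, n_post, cfg.thin,
            cond_idx, fb, ratings, slot_map, init_idx, fixed,
            n_a, n_v, model.is_mean,
            cfg.prior_init_mean, cfg.prior_init_sd, cfg.prior_sigma_scale,
        )
        cdraws, pw = _constrain_and_pointwise(
            draws, cond_idx, fb, ratings, slot_map, init_idx, fixed,
            n_a, n_v, model.is_mean,
        )
        all_draws[ch] = cdraws
        all_pw[ch] = pw
        acc += a
    return all_draws, all_pw.reshape(-1, len(ratings)), acc / cfg.n_chains


def fit_subject(
    model: ModelSpec,
    data: BehavioralDataset,
    cfg: SamplerConfig | None = None,
    backend=None,
) -> PosteriorFit:
    """Fit one model to one subject's ratings; deterministic given cfg.seed.

    Returns the posterior draws on the constrained scale together with the
    pointwise log-likelihood evaluated at every retained draw (the input
    to PSIS-LOO) and per-parameter R-hat / ESS diagnostics.
    """
    cfg = cfg or SamplerConfig()
    if len(data.exp_ratings) == 0:
        raise ValueError("cannot fit an empty dataset")
    if backend is None:
        backend = _metropolis_backend
    draws, pointwise, accept = backend(model, data, cfg)
    if not np.all(np.isfinite(pointwise)):
        raise RuntimeError(
            f"non-finite pointwise log-likelihood for {data.subject_id}/{model.name}"
        )
    names = model.param_names()
    rhat = {p: compute_rhat(draws[:, :, j]) for j, p in enumerate(names)}
    ess = {p: compute_ess(draws[:, :, j]) for j, p in enumerate(names)}
    return PosteriorFit(
        subject_id=data.subject_id,
        model_name=model.name,
        param_names=names,
        draws=draws,
        pointwise_loglik=pointwise,
        rhat=rhat,
        ess=ess,
        accept_rate=accept,
    )


def fit_cohort(
    datasets: list[BehavioralDataset],
    models: list[ModelSpec],
    cfg: SamplerConfig | None = None,
    backend=None,
) -> dict[str, dict[str, PosteriorFit]]:
    """Fit every model to every subject; returns fits[subject][model]."""
    out: dict[str, dict[str, PosteriorFit]] = {}
    for data in datasets:
        out[data.subject_id] = {
            m.name: fit_subject(m, data, cfg, backend=backend) for m in models
        }
    return out


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def apply_exclusions(
    fits: dict[str, dict[str, PosteriorFit]], threshold: float = 1.1
) -> tuple[dict[str, dict[str, PosteriorFit]], list[dict]]:
    """Exclude subjects with any parameter's R-hat above ``threshold``
    (or undefined) in any fitted model.

    Returns the retained fits and a report listing, per excluded subject,
    the offending model, parameter and R-hat value.
    """
    retained: dict[str, dict[str, PosteriorFit]] = {}
    excluded: list[dict] = []
    for sid, per_model in fits.items():
        reasons = []
        for mname, fit in per_model.items():
            for p, r in fit.rhat.items():
                if np.isnan(r) or r > threshold:
                    reasons.append(
                        {"subject_id": sid, "model": mname, "param": p, "rhat": r}
                    )
        if reasons:
            excluded.extend(reasons)
        else:
            retained[sid] = per_model
    return retained, excluded


def flag_implausible_parameters(
    fits: dict[str, dict[str, PosteriorFit]],
    model_name: str,
    n_sd: float = 10.0,
) -> pd.DataFrame:
    """Flag (never exclude) subjects whose posterior-mean learning rates sit
    more than ``n_sd`` cohort SDs from the cohort mean under one model."""
    rows = []
    for sid, per_model in fits.items():
        fit = per_model[model_name]
        for p, v in fit.posterior_mean.items():
            if p.startswith("alpha"):
                rows.append({"subject_id": sid, "param": p, "value": v})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(z=[], flagged=[])
    stats_ = df.groupby("param")["value"].agg(["mean", "std"])
    df = df.join(stats_, on="param")
    df["z"] = (df["value"] - df["mean"]) / df["std"].replace(0.0, np.nan)
    df["flagged"] = df["z"].abs() > n_sd
    return df[["subject_id", "param", "value", "z", "flagged"]]
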