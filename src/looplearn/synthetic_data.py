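"""Simulation of the performance-feedback learning task and synthetic cohorts.

The task delivers rigged percentile feedback in two ability conditions:
a Low Ability stream distributed around the 35th percentile and a High
Ability stream around the 65th percentile (both SD ~= 16, truncated to
[1, 60] and [40, 99] respectively), interleaved so that no more than two
consecutive trials share a condition.  Agent experiments cross this with
a Self/Other factor (25 trials per cell); audience experiments use the
two self-related cells only (30 trials each).

Synthetic subjects are delta-rule learners (see
:mod:`looplearn.learning_models`) whose ratings are noisy readouts of the
latent expectation, and cohorts come with trait scores (self-esteem,
social anxiety) coupled to each subject's true learning asymmetry through
a Gaussian copula, so trait-association analyses are testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .learning_models import (
    ModelSpec,
    ParameterSet,
    conditions_for,
    family_of,
    get_model,
    predict_trajectory,
)

__all__ = [
    "FEEDBACK_RANGES",
    "FEEDBACK_TARGET_MEANS",
    "FEEDBACK_TARGET_SD",
    "FeedbackSchedule",
    "TrialDesign",
    "BehavioralDataset",
    "Cohort",
    "PopulationSpec",
    "TraitCoupling",
    "DEFAULT_AGENT_POPULATION",
    "DEFAULT_AUDIENCE_POPULATION",
    "REPLICATION_AGENT_POPULATION",
    "default_population",
    "generate_feedback_schedule",
    "build_design",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: feedback percentile range per ability condition
FEEDBACK_RANGES = {"low": (1, 60), "high": (40, 99)}
#: target sample mean of the delivered feedback per condition
FEEDBACK_TARGET_MEANS = {"low": 35.0, "high": 65.0}
#: target sample SD of the delivered feedback (both conditions)
FEEDBACK_TARGET_SD = 16.0

TRIALS_PER_CONDITION = {"agent": 25, "audience": 30}

#: maximum number of consecutive trials of the same condition
MAX_RUN = 2


# ---------------------------------------------------------------------------
# feedback schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedbackSchedule:
    """Fixed feedback percentiles for one ability condition."""

    ability_condition: str
    feedback: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.feedback)


@lru_cache(maxsize=None)
def _calibrated_parent(ability: str) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose truncation to the condition's range
    has the target mean and SD.

    Truncation pulls the mean toward the wide side and shrinks the SD, so
    sampling N(35, 16) directly and rejecting out-of-range draws would
    deliver mean ~33.7 and SD ~13.4 in the low condition.  Solving for the
    parent moments makes the delivered feedback itself match the stated
    mean/SD.
    """
    lo, hi = FEEDBACK_RANGES[ability]
    m, s = FEEDBACK_TARGET_MEANS[ability], FEEDBACK_TARGET_SD

    def resid(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        d = stats.truncnorm(a, b, loc=mu, scale=sig)
        return [d.mean() - m, d.std() - s]

    sol, info, ier, msg = optimize.fsolve(
        resid, x0=[m, np.log(s * 1.5)], full_output=True
    )
    if ier != 1:  # pragma: no cover - calibration is fixed and solvable
        raise RuntimeError(f"feedback calibration failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def generate_feedback_schedule(
    ability: str, n_trials: int, seed: int
) -> FeedbackSchedule:
    """Draw a feedback schedule by rejection from a calibrated normal.

    Values are sampled from the parent normal, rejected outside the
    condition's percentile range, and rounded to whole percentiles (the
    task displays integer percentiles).  Deterministic given ``seed``.
    """
    if ability not in FEEDBACK_RANGES:
        raise ValueError(
            f"unknown ability label {ability!r}; expected 'high' or 'low'"
        )
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = FEEDBACK_RANGES[ability]
    mu, sig = _calibrated_parent(ability)
    rng = np.random.default_rng(seed)
    out = np.empty(n_trials)
    filled = 0
    while filled < n_trials:
        draw = rng.normal(mu, sig, size=max(2 * (n_trials - filled), 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n_trials - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return FeedbackSchedule(
        ability_condition=ability, feedback=np.rint(out).astype(np.int64)
    )


# ---------------------------------------------------------------------------
# trial designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Condition sequence and feedback percentiles for one subject."""

    experiment: str
    agent: np.ndarray       # "self" / "other" per trial
    ability: np.ndarray     # "high" / "low" per trial
    feedback: np.ndarray    # integer percentile per trial
    cond_idx: np.ndarray    # index into conditions_for(experiment)

    @property
    def n_trials(self) -> int:
        return len(self.feedback)

    @property
    def conditions(self) -> tuple[tuple[str, str], ...]:
        return conditions_for(self.experiment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "agent": self.agent,
                "ability": self.ability,
                "feedback": self.feedback,
            }
        )


def _interleave(n_cond: int, per_cond: int, rng: np.random.Generator,
                max_tries: int = 2000) -> np.ndarray:
    """Condition order with exact counts and runs capped at MAX_RUN.

    Sequential construction: at each position draw among the conditions
    that still have trials left and would not create a run of three,
    weighted by remaining counts; restart on the rare dead end.
    """
    total = n_cond * per_cond
    for _ in range(max_tries):
        remaining = np.full(n_cond, per_cond)
        seq = np.empty(total, dtype=np.int64)
        ok = True
        for pos in range(total):
            allowed = remaining > 0
            if pos >= MAX_RUN and seq[pos - 1] == seq[pos - 2]:
                allowed = allowed.copy()
                allowed[seq[pos - 1]] = False
            w = remaining * allowed
            tot = w.sum()
            if tot == 0:
                ok = False
                break
            seq[pos] = rng.choice(n_cond, p=w / tot)
            remaining[seq[pos]] -= 1
        if ok:
            return seq
    raise RuntimeError(
        f"could not interleave {n_cond} conditions x {per_cond} trials "
        f"under the max-run-of-{MAX_RUN} constraint"
    )


def build_design(
    experiment: str, seed: int, trials_per_condition: int | None = None
) -> TrialDesign:
    """Generate a full task design for one subject.

    The condition order satisfies the exact per-cell trial counts and the
    max-run-of-two constraint; feedback values are filled per condition by
    :func:`generate_feedback_schedule` from seeds spawned off ``seed``.
    """
    fam = family_of(experiment)
    conds = conditions_for(experiment)
    per_cond = trials_per_condition or TRIALS_PER_CONDITION[fam]
    ss = np.random.SeedSequence(seed)
    order_seed, *fb_seeds = ss.spawn(1 + len(conds))
    rng = np.random.default_rng(order_seed)
    seq = _interleave(len(conds), per_cond, rng)

    feedback = np.empty(len(seq), dtype=np.int64)
    for c, (_, ability) in enumerate(conds):
        sched = generate_feedback_schedule(ability, per_cond, fb_seeds[c])
        feedback[seq == c] = sched.feedback
    agent = np.asarray([conds[c][0] for c in seq], dtype=object)
    ability_arr = np.asarray([conds[c][1] for c in seq], dtype=object)
    return TrialDesign(
        experiment=experiment,
        agent=agent,
        ability=ability_arr,
        feedback=feedback,
        cond_idx=seq,
    )


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass
class BehavioralDataset:
    """Observed expectation ratings joined to a design; unit of model fitting."""

    subject_id: str
    group: str
    design: TrialDesign
    exp_ratings: np.ndarray

    def __post_init__(self):
        self.exp_ratings = np.asarray(self.exp_ratings, dtype=float)
        if self.exp_ratings.shape[0] != self.design.n_trials:
            raise ValueError("need one rating per design trial")
        if np.any(self.exp_ratings < 0) or np.any(self.exp_ratings > 100):
            raise ValueError("ratings must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        df = self.design.to_frame()
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "group", self.group)
        df["exp_rating"] = self.exp_ratings
        return df


def simulate_subject(
    design: TrialDesign,
    model: ModelSpec,
    params: ParameterSet,
    seed: int,
    subject_id: str = "sim",
    group: str | None = None,
) -> BehavioralDataset:
    """Simulate one subject's ratings from a learning model.

    Latent expectations evolve by the model's delta rule against the
    design's feedback; observed ratings add Gaussian noise of scale
    ``params.noise_sd`` and are clipped to [0, 100].  With ``noise_sd=0``
    the ratings equal the latent trajectory exactly.
    """
    traj = predict_trajectory(model, params, design)
    rng = np.random.default_rng(seed)
    ratings = traj.latent_exp.copy()
    if params.noise_sd > 0:
        ratings = ratings + rng.normal(0.0, params.noise_sd, size=len(ratings))
    np.clip(ratings, 0.0, 100.0, out=ratings)
    return BehavioralDataset(
        subject_id=subject_id,
        group=group or design.experiment,
        design=design,
        exp_ratings=ratings,
    )


def _beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(
            f"Beta distribution with mean {mean} cannot have SD {sd}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class PopulationSpec:
    """Population distributions for subject-level true parameters.

    Learning rates are drawn from Beta distributions matched to the given
    (mean, sd) per slot, which keeps them in [0, 1].  Initial expectations
    are truncated-normal around the scale midpoint; the observation noise
    SD is shared across subjects.
    """

    alpha_moments: dict[str, tuple[float, float]]
    init_mean: float = 50.0
    init_sd: float = 8.0
    noise_sd: float = 10.0

    def sample_alphas(self, slot_names, n, rng) -> np.ndarray:
        out = np.empty((n, len(slot_names)))
        for j, name in enumerate(slot_names):
            m, s = self.alpha_moments[name]
            a, b = _beta_from_moments(m, s)
            out[:, j] = rng.beta(a, b, size=n)
        return out

    def sample_inits(self, n_init, n, rng) -> np.ndarray:
        a = (0.0 - self.init_mean) / self.init_sd
        b = (100.0 - self.init_mean) / self.init_sd
        d = stats.truncnorm(a, b, loc=self.init_mean, scale=self.init_sd)
        return d.rvs(size=(n, n_init), random_state=rng)


#: learning-rate population moments echoing the fitted group means/SDs of
#: the first agent experiment (self: pos 0.12/0.06, neg 0.14/0.09;
#: other: pos 0.11/0.08, neg 0.10/0.07)
DEFAULT_AGENT_POPULATION = PopulationSpec(
    alpha_moments={
        "alpha_pos_self": (0.12, 0.06),
        "alpha_neg_self": (0.14, 0.09),
        "alpha_pos_other": (0.11, 0.08),
        "alpha_neg_other": (0.10, 0.07),
    }
)

#: audience-family counterpart (valence model, private-group means/SDs)
DEFAULT_AUDIENCE_POPULATION = PopulationSpec(
    alpha_moments={"alpha_pos": (0.07, 0.05), "alpha_neg": (0.10, 0.08)}
)

#: replication-experiment self/other valence means/SDs (larger asymmetry,
#: alpha_neg_self - alpha_pos_self = 0.06)
REPLICATION_AGENT_POPULATION = PopulationSpec(
    alpha_moments={
        "alpha_pos_self": (0.09, 0.05),
        "alpha_neg_self": (0.15, 0.09),
        "alpha_pos_other": (0.12, 0.08),
        "alpha_neg_other": (0.11, 0.07),
    }
)

#: plausible population moments for every learning-rate slot in the model
#: space; valence slots echo fitted group values, the rest sit at the same
#: overall learning-rate level with mild condition differences
_SLOT_MOMENTS = {
    "alpha_uni": (0.12, 0.07),
    "alpha_uni_self": (0.13, 0.07),
    "alpha_uni_other": (0.10, 0.07),
    "alpha_high": (0.10, 0.06),
    "alpha_low": (0.14, 0.08),
    "alpha_high_self": (0.10, 0.06),
    "alpha_low_self": (0.15, 0.08),
    "alpha_high_other": (0.09, 0.06),
    "alpha_low_other": (0.12, 0.07),
    "alpha_pos": (0.10, 0.06),
    "alpha_neg": (0.16, 0.09),
    "alpha_pos_self": (0.12, 0.06),
    "alpha_neg_self": (0.14, 0.09),
    "alpha_pos_other": (0.11, 0.08),
    "alpha_neg_other": (0.10, 0.07),
}


def default_population(model: ModelSpec, noise_sd: float = 10.0) -> PopulationSpec:
    """A realistic population spec for any model in the space."""
    return PopulationSpec(
        alpha_moments={s: _SLOT_MOMENTS[s] for s in model.slot_names},
        noise_sd=noise_sd,
    )


@dataclass
class TraitCoupling:
    """Target correlations between traits and the true self valence bias."""

    self_esteem_r: float = 0.44
    social_anxiety_r: float = 0.0
    self_esteem_marginal: tuple[float, float] = (6.0, 1.0)   # SDQ-like scale
    social_anxiety_marginal: tuple[float, float] = (20.0, 12.0)  # SIAS-like

    def __post_init__(self):
        for r in (self.self_esteem_r, self.social_anxiety_r):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"trait coupling correlation {r} outside [-1, 1]")


def _default_coupling(experiment: str) -> TraitCoupling:
    # negative anxiety coupling only under a (potential) audience
    public = experiment.endswith("public")
    return TraitCoupling(social_anxiety_r=-0.39 if public else 0.0)


@dataclass
class Cohort:
    """A simulated cohort: per-subject data, traits, and ground truth."""

    experiment: str
    model: ModelSpec
    datasets: list[BehavioralDataset]
    traits: pd.DataFrame
    true_params: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.datasets)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([d.to_frame() for d in self.datasets], ignore_index=True)


def _copula_trait(z_bias, r, marginal, rng):
    mean, sd = marginal
    z = r * z_bias + np.sqrt(1.0 - r * r) * rng.standard_normal(len(z_bias))
    return mean + sd * z


def simulate_cohort(
    n_subjects: int,
    experiment: str,
    model_name: str | None = None,
    param_population: PopulationSpec | None = None,
    trait_coupling: TraitCoupling | None = None,
    seed: int = 0,
    trials_per_condition: int | None = None,
    shared_design: bool = True,
) -> Cohort:
    """Simulate a cohort of delta-rule learners with coupled trait scores.

    True per-subject parameters are drawn from the population spec; trait
    scores are generated through a Gaussian copula on the rank-normal
    score of each subject's true self valence bias, at the requested
    correlations.  ``shared_design=True`` gives every subject the same
    fixed design (as in the task, where feedback orders were fixed across
    participants).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    fam = family_of(experiment)
    if model_name is None:
        model_name = "M6_valence_SO" if fam == "agent" else "M3_valence"
    model = get_model(experiment, model_name)
    pop = param_population or (
        DEFAULT_AGENT_POPULATION if fam == "agent" else DEFAULT_AUDIENCE_POPULATION
    )
    missing = [s for s in model.slot_names if s not in pop.alpha_moments]
    if missing:
        raise ValueError(f"population spec lacks moments for slots {missing}")
    coupling = trait_coupling or _default_coupling(experiment)

    ss = np.random.SeedSequence(seed)
    key = ss.generate_state(6, dtype=np.uint32)
    rng = np.random.default_rng(int(key[0]))
    design_seed = int(key[1])

    alphas = pop.sample_alphas(model.slot_names, n_subjects, rng)
    inits = pop.sample_inits(model.n_init_params, n_subjects, rng)

    datasets = []
    rows = []
    design = build_design(experiment, design_seed, trials_per_condition)
    for i in range(n_subjects):
        if not shared_design:
            design = build_design(experiment, design_seed + 1 + i, trials_per_condition)
        sid = f"sub{i + 1:03d}"
        params = ParameterSet(
            alphas=alphas[i], init_values=inits[i], noise_sd=pop.noise_sd
        )
        datasets.append(
            simulate_subject(
                design, model, params, seed=int(key[2]) + i, subject_id=sid,
                group=experiment,
            )
        )
        row = {"subject_id": sid}
        row.update(dict(zip(model.slot_names, alphas[i])))
        row.update({f"init_{j}": inits[i, j] for j in range(inits.shape[1])})
        row["noise_sd"] = pop.noise_sd
        rows.append(row)
    true_params = pd.DataFrame(rows)

    # true self valence bias drives the trait copula (valence models only;
    # other generating models have no asymmetry, so traits are uncoupled)
    pos = "alpha_pos_self" if fam == "agent" else "alpha_pos"
    neg = "alpha_neg_self" if fam == "agent" else "alpha_neg"
    if pos in true_params and neg in true_params:
        bias = (true_params[pos] - true_params[neg]) / (
            true_params[pos] + true_params[neg]
        )
        true_params["valence_bias_self"] = bias
        z_bias = stats.norm.ppf((stats.rankdata(bias) - 0.5) / n_subjects)
    else:
        true_params["valence_bias_self"] = np.nan
        z_bias = np.zeros(n_subjects)
    trait_rng = np.random.default_rng(int(key[3]))
    traits = pd.DataFrame(
        {
            "subject_id": true_params["subject_id"],
            "self_esteem": _copula_trait(
                z_bias, coupling.self_esteem_r, coupling.self_esteem_marginal, trait_rng
            ),
            "social_anxiety": _copula_trait(
                z_bias, coupling.social_anxiety_r, coupling.social_anxiety_marginal,
                trait_rng,
            ),
        }
    )
    return Cohort(
        experiment=experiment,
        model=model,
        datasets=datasets,
        traits=traits,
        true_params=true_params,
    )


# ---------------------------------------------------------------------------
# disk round-trip (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(out / "trials.csv", index=False)
    cohort.traits.to_csv(out / "traits.csv", index=False)
    cohort.true_params.to_csv(out / "true_params.csv", index=False)
    meta = {"experiment": cohort.experiment, "model": cohort.model.name}
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))


def read_cohort_trials(path: str | Path, experiment: str) -> list[BehavioralDataset]:
    """Load per-subject datasets from a trials CSV written by write_cohort."""
    df = pd.read_csv(path)
    conds = conditions_for(experiment)
    lut = {c: i for i, c in enumerate(conds)}
    datasets = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        design = TrialDesign(
            experiment=experiment,
            agent=sub["agent"].to_numpy(dtype=object),
            ability=sub["ability"].to_numpy(dtype=object),
            feedback=sub["feedback"].to_numpy(dtype=np.int64),
            cond_idx=np.asarray(
                [lut[(a, b)] for a, b in zip(sub["agent"], sub["ability"])],
                dtype=np.int64,
            ),
        )
        datasets.append(
            BehavioralDataset(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                design=design,
                exp_ratings=sub["exp_rating"].to_numpy(dtype=float),
            )
        )
    return datasets


def read_cohort(indir: str | Path) -> Cohort:
    ind = Path(indir)
    meta = json.loads((ind / "cohort.json").read_text())
    datasets = read_cohort_trials(ind / "trials.csv", meta["experiment"])
    return Cohort(
        experiment=meta["experiment"],
        model=get_model(meta["experiment"], meta["model"]),
        datasets=datasets,
        traits=pd.read_csv(ind / "traits.csv"),
        true_params=pd.read_csv(ind / "true_params.csv"),
    )
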