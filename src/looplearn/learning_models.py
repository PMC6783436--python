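"""Delta-rule learning models for trial-by-trial performance-expectation data.

The model space covers Rescorla–Wagner learners whose learning rate may
depend on the ability condition (high/low), the valence of the prediction
error (positive/negative), and the agent (self/other), plus a no-learning
Mean model that predicts a constant expectation per condition.

Each model maintains one latent expectation per (agent x ability) condition.
On a trial of condition c with feedback FB_t the latent state evolves as

    EXP_{t+1} = EXP_t + alpha * PE_t,      PE_t = FB_t - EXP_t,

where ``alpha`` is looked up from the trial context via the model's slot
rule.  Observed ratings are modelled as Gaussian readouts of the latent
expectation with a single per-subject noise scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = [
    "AGENT_EXPERIMENTS",
    "AUDIENCE_EXPERIMENTS",
    "ModelSpec",
    "ParameterSet",
    "PredictedTrajectory",
    "conditions_for",
    "log_likelihood_pointwise",
    "model_space",
    "get_model",
    "predict_trajectory",
    "resolve_alpha",
    "rw_update",
]

AGENT_EXPERIMENTS = ("agent_private", "agent_public")
AUDIENCE_EXPERIMENTS = ("audience_private", "audience_public")

#: canonical (agent, ability) condition order per experiment family
_AGENT_CONDS = (("self", "high"), ("self", "low"), ("other", "high"), ("other", "low"))
_AUDIENCE_CONDS = (("self", "high"), ("self", "low"))

def family_of(experiment: str) -> str:
    if experiment in AGENT_EXPERIMENTS:
        return "agent"
    if experiment in AUDIENCE_EXPERIMENTS:
        return "audience"
    raise ValueError(f"unknown experiment label: {experiment!r}")


def conditions_for(experiment: str) -> tuple[tuple[str, str], ...]:
    """Canonical ordered (agent, ability) cells for an experiment label."""
    return _AGENT_CONDS if family_of(experiment) == "agent" else _AUDIENCE_CONDS


# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One member of the model space.

    ``slot_map[c, s]`` gives the learning-rate slot used on a trial of
    condition index ``c`` with prediction-error sign index ``s`` (0 for
    PE >= 0, 1 for PE < 0).  The Mean model has no slots (``is_mean``).
    """

    name: str
    family: str                     # "agent" | "audience"
    slot_names: tuple[str, ...]
    slot_map: tuple[tuple[int, int], ...]
    init_scheme: str = "fitted_per_condition"
    is_mean: bool = False

    @property
    def conditions(self) -> tuple[tuple[str, str], ...]:
        return _AGENT_CONDS if self.family == "agent" else _AUDIENCE_CONDS

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_alpha_slots(self) -> int:
        return len(self.slot_names)

    @property
    def agents(self) -> tuple[str, ...]:
        return ("self", "other") if self.family == "agent" else ("self",)

    @property
    def n_init_params(self) -> int:
        if self.is_mean:
            return 0
        if self.init_scheme == "fitted_per_condition":
            return self.n_conditions
        if self.init_scheme == "fitted_combined":
            return len(self.agents)
        if self.init_scheme == "fixed_first_rating":
            return 0
        raise ValueError(f"unknown init scheme: {self.init_scheme!r}")

    def slot_map_array(self) -> np.ndarray:
        return np.asarray(self.slot_map, dtype=np.int64)

    def init_index(self) -> np.ndarray:
        """Map condition index -> index into the init parameter vector."""
        if self.init_scheme == "fitted_per_condition":
            return np.arange(self.n_conditions, dtype=np.int64)
        if self.init_scheme == "fitted_combined":
            agents = self.agents
            return np.asarray(
                [agents.index(a) for a, _ in self.conditions], dtype=np.int64
            )
        raise ValueError(
            f"init scheme {self.init_scheme!r} has no fitted init parameters"
        )

    def param_names(self) -> list[str]:
        names = list(self.slot_names)
        if self.is_mean:
            names += [f"mean_{a}_{ab}" for a, ab in self.conditions]
        elif self.init_scheme == "fitted_per_condition":
            names += [f"init_{a}_{ab}" for a, ab in self.conditions]
        elif self.init_scheme == "fitted_combined":
            names += [f"init_{a}" for a in self.agents]
        return names + ["noise_sd"]

    def validate_params(self, params: "ParameterSet") -> None:
        if self.is_mean:
            if params.condition_means is None or len(params.condition_means) != self.n_conditions:
                raise ValueError(
                    f"{self.name} requires {self.n_conditions} condition means"
                )
            return
        if len(params.alphas) != self.n_alpha_slots:
            raise ValueError(
                f"{self.name} has {self.n_alpha_slots} learning-rate slots, "
                f"got {len(params.alphas)} alphas"
            )
        a = np.asarray(params.alphas, float)
        if np.any(a < 0.0) or np.any(a > 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.init_scheme != "fixed_first_rating":
            if params.init_values is None or len(params.init_values) != self.n_init_params:
                raise ValueError(
                    f"{self.name} with scheme {self.init_scheme!r} requires "
                    f"{self.n_init_params} initial values"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "family": self.family,
                "slot_names": list(self.slot_names),
                "slot_map": [list(r) for r in self.slot_map],
                "init_scheme": self.init_scheme,
                "is_mean": self.is_mean,
            }
        )

    @staticmethod
    def from_json(s: str) -> "ModelSpec":
        d = json.loads(s)
        return ModelSpec(
            name=d["name"],
            family=d["family"],
            slot_names=tuple(d["slot_names"]),
            slot_map=tuple(tuple(r) for r in d["slot_map"]),
            init_scheme=d["init_scheme"],
            is_mean=d["is_mean"],
        )


@dataclass
class ParameterSet:
    """Concrete parameter values for one model.

    alphas          learning rates in [0, 1], one per slot
    init_values     initial expectations on the rating scale, per the
                    model's init scheme (ignored by the Mean model)
    condition_means Mean-model constants, one per condition
    noise_sd        observation noise SD on the rating scale (> 0 for
                    likelihood evaluation)
    """

    alphas: np.ndarray = field(default_factory=lambda: np.empty(0))
    init_values: np.ndarray | None = None
    condition_means: np.ndarray | None = None
    noise_sd: float = 8.0

    def __post_init__(self):
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        if self.init_values is not None:
            self.init_values = np.atleast_1d(np.asarray(self.init_values, dtype=float))
        if self.condition_means is not None:
            self.condition_means = np.atleast_1d(
                np.asarray(self.condition_means, dtype=float)
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphas": self.alphas.tolist(),
                "init_values": None if self.init_values is None else self.init_values.tolist(),
                "condition_means": None
                if self.condition_means is None
                else self.condition_means.tolist(),
                "noise_sd": self.noise_sd,
            }
        )

    @staticmethod
    def from_json(s: str) -> "ParameterSet":
        d = json.loads(s)
        return ParameterSet(
            alphas=np.asarray(d["alphas"], float),
            init_values=None if d["init_values"] is None else np.asarray(d["init_values"], float),
            condition_means=None
            if d["condition_means"] is None
            else np.asarray(d["condition_means"], float),
            noise_sd=d["noise_sd"],
        )


@dataclass(frozen=True)
class PredictedTrajectory:
    """Latent expectations and prediction errors, one entry per trial."""

    latent_exp: np.ndarray
    pe: np.ndarray


def _agent_spec(name, slot_names, slot_map):
    return ModelSpec(name=name, family="agent", slot_names=slot_names, slot_map=slot_map)


def _audience_spec(name, slot_names, slot_map):
    return ModelSpec(name=name, family="audience", slot_names=slot_names, slot_map=slot_map)


# condition order (agent family): self/high, self/low, other/high, other/low
_AGENT_MODELS = (
    _agent_spec("M1_unity", ("alpha_uni",), ((0, 0),) * 4),
    _agent_spec(
        "M2_ability",
        ("alpha_high", "alpha_low"),
        ((0, 0), (1, 1), (0, 0), (1, 1)),
    ),
    _agent_spec(
        "M3_valence",
        ("alpha_pos", "alpha_neg"),
        ((0, 1), (0, 1), (0, 1), (0, 1)),
    ),
    _agent_spec(
        "M4_unity_SO",
        ("alpha_uni_self", "alpha_uni_other"),
        ((0, 0), (0, 0), (1, 1), (1, 1)),
    ),
    _agent_spec(
        "M5_ability_SO",
        ("alpha_high_self", "alpha_low_self", "alpha_high_other", "alpha_low_other"),
        ((0, 0), (1, 1), (2, 2), (3, 3)),
    ),
    _agent_spec(
        "M6_valence_SO",
        ("alpha_pos_self", "alpha_neg_self", "alpha_pos_other", "alpha_neg_other"),
        ((0, 1), (0, 1), (2, 3), (2, 3)),
    ),
    ModelSpec(
        name="M_mean", family="agent", slot_names=(), slot_map=(), is_mean=True
    ),
)

_AUDIENCE_MODELS = (
    _audience_spec("M1_unity", ("alpha_uni",), ((0, 0),) * 2),
    _audience_spec("M2_ability", ("alpha_high", "alpha_low"), ((0, 0), (1, 1))),
    _audience_spec("M3_valence", ("alpha_pos", "alpha_neg"), ((0, 1), (0, 1))),
    ModelSpec(
        name="M_mean", family="audience", slot_names=(), slot_map=(), is_mean=True
    ),
)


def model_space(experiment: str) -> list[ModelSpec]:
    """The full model space compared for one experiment.

    Agent experiments: six delta-rule learners (unity / ability / valence,
    each with and without an own-vs-other split) plus the four-mean Mean
    model.  Audience experiments: unity / ability / valence plus the
    two-mean Mean model.
    """
    if family_of(experiment) == "agent":
        return list(_AGENT_MODELS)
    return list(_AUDIENCE_MODELS)


def get_model(experiment: str, name: str) -> ModelSpec:
    for m in model_space(experiment):
        if m.name == name:
            return m
    raise ValueError(f"no model {name!r} in the {experiment!r} model space")


# ---------------------------------------------------------------------------
# core update / trajectory kernels
# ---------------------------------------------------------------------------

def rw_update(exp: float, fb: float, alpha: float) -> float:
    """Single Rescorla–Wagner update: exp + alpha * (fb - exp)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate must lie in [0, 1], got {alpha}")
    return exp + alpha * (fb - exp)


def resolve_alpha(model: ModelSpec, context: tuple[str, str, str], params: ParameterSet) -> float:
    """Learning rate used on a trial with the given (agent, ability, pe_sign).

    ``pe_sign`` is "positive" or "negative"; a zero prediction error is
    routed to the positive slot by convention.
    """
    if model.is_mean:
        raise ValueError("the Mean model has no learning rate")
    agent, ability, pe_sign = context
    try:
        c = model.conditions.index((agent, ability))
    except ValueError:
        raise ValueError(
            f"condition ({agent}, {ability}) not in the {model.family} family"
        ) from None
    if pe_sign not in ("positive", "negative"):
        raise ValueError(f"pe_sign must be 'positive' or 'negative', got {pe_sign!r}")
    s = 0 if pe_sign == "positive" else 1
    return float(params.alphas[model.slot_map[c][s]])


@njit(cache=True)
def _traj_kernel(cond_idx, feedback, slot_map, alphas, cond_inits):
    n = cond_idx.shape[0]
    latent = np.empty(n)
    state = cond_inits.copy()
    for t in range(n):
        c = cond_idx[t]
        e = state[c]
        latent[t] = e
        pe = feedback[t] - e
        s = 0 if pe >= 0.0 else 1
        state[c] = e + alphas[slot_map[c, s]] * pe
    return latent


@njit(cache=True)
def _loglik_kernel(latent, ratings, noise_sd):
    n = latent.shape[0]
    out = np.empty(n)
    c = -math.log(noise_sd) - 0.5 * math.log(2.0 * math.pi)
    inv2 = 0.5 / (noise_sd * noise_sd)
    for t in range(n):
        r = ratings[t] - latent[t]
        out[t] = c - r * r * inv2
    return out


def _effective_inits(model: ModelSpec, params: ParameterSet, data=None) -> np.ndarray:
    """Per-condition initial expectations implied by the init scheme."""
    if model.init_scheme == "fixed_first_rating":
        if data is None:
            raise ValueError(
                "init scheme 'fixed_first_rating' needs observed data to "
                "anchor the initial expectations"
            )
        inits = np.empty(model.n_conditions)
        for c in range(model.n_conditions):
            idx = np.nonzero(data.design.cond_idx == c)[0]
            if idx.size == 0:
                raise ValueError(f"design has no trials for condition {c}")
            inits[c] = data.exp_ratings[idx[0]]
        return inits
    return params.init_values[model.init_index()]


def predict_trajectory(
    model: ModelSpec, params: ParameterSet, design, data=None
) -> PredictedTrajectory:
    """Latent expectation and prediction error for every trial of a design.

    A separate latent state is kept per (agent x ability) condition and is
    updated only on that condition's trials.  The Mean model predicts its
    condition mean on every trial.  ``data`` is only needed for the
    ``fixed_first_rating`` init scheme.
    """
    model.validate_params(params)
    fb = np.asarray(design.feedback, dtype=float)
    cond_idx = np.asarray(design.cond_idx, dtype=np.int64)
    if cond_idx.max(initial=-1) >= model.n_conditions:
        raise ValueError(
            f"design references condition index {int(cond_idx.max())} but "
            f"{model.name} has only {model.n_conditions} conditions"
        )
    if model.is_mean:
        latent = params.condition_means[cond_idx]
    else:
        inits = _effective_inits(model, params, data)
        latent = _traj_kernel(
            cond_idx, fb, model.slot_map_array(), params.alphas, inits
        )
    return PredictedTrajectory(latent_exp=latent, pe=fb - latent)


def log_likelihood_pointwise(
    model: ModelSpec, params: ParameterSet, data
) -> np.ndarray:
    """Per-trial Gaussian log-density of the observed ratings.

    Trial t contributes N(rating_t | EXP_t, noise_sd^2) on the log scale;
    the sum over trials is the joint log-likelihood.
    """
    if params.noise_sd <= 0:
        raise ValueError("noise_sd must be positive for likelihood evaluation")
    ratings = np.asarray(data.exp_ratings, dtype=float)
    if ratings.shape[0] != len(data.design.feedback):
        raise ValueError("need exactly one observed rating per design trial")
    traj = predict_trajectory(model, params, data.design, data=data)
    return _loglik_kernel(traj.latent_exp, ratings, float(params.noise_sd))
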