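"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators are provided, serving different validation needs:

1. **Behavioral agents** (:func:`simulate_cohort`): each simulated
   child plays the full gambling task through the engine. Deck choice
   follows an inverse-probit-linked linear predictor (intercept, block
   trend, gender, age, intervention-after-video effects, plus
   participant-level random intercept and slope), and performance
   estimates follow an ordered-threshold model whose latent optimism
   responds to the most recent payoff change, drifts down over
   occasions, and carries a gender x occasion volatility pattern
   (female dip at the 2nd estimate, spike at the 4th). These policies
   are the package's own construction — no behavioral generative model
   exists in the study protocol — with defaults chosen so cohort-level
   trajectories are qualitatively realistic: a rising safe-card ratio,
   v-shaped payoffs, declining male overconfidence, and volatile,
   payoff-coupled female estimates.

2. **Model-based outcome tables** (:func:`simulate_outcome_table`):
   covariates are laid out exactly as in the study cohort (58
   participants, 29 per arm, 27 female, 16 aged >= 5y) and outcomes are
   drawn directly from the mixed model being fitted, with known
   coefficients. This is the generator parameter-recovery tests use;
   its default ground-truth fixed effects sit in the effect-size
   regime the analysis targets (e.g. a ~2.9-sticker female payoff
   advantage, a strong negative time trend in overconfidence on the
   probit scale).

Every generator takes an explicit seed and serializes its generating
coefficients (:class:`GroundTruth`) alongside the cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import InvalidConfigError
from .inference import MODEL_SPECS, PROBIT, ModelSpec, build_design
from .task import (
    DONT_KNOW,
    LESS,
    MORE,
    RISKY,
    SAFE,
    SAME,
    Cohort,
    EstimateRecord,
    GameConfig,
    INTERVENTION_AFTER_BLOCK,
    ParticipantSession,
    run_session,
)


@dataclass(frozen=True)
class AgentParams:
    """Behavioral policy coefficients (probit / ordered-threshold scale).

    Choice model: P(SAFE on block b) = Phi(intercept + trend*b +
    female + age + intervention*post-video + u_i0 + u_i1*b).

    Estimate model: latent optimism = intercept + payoff_coupling *
    (last block payoff change) + time_trend * occasion + female
    volatility shift, cut at (less_cut, more_cut) into LESS / SAME /
    MORE; an independent dont_know_rate chance yields DONT_KNOW.
    """

    choice_intercept: float = -0.15
    choice_trend: float = 0.06
    choice_female: float = 0.30
    choice_age: float = 0.10
    choice_intervention_post: float = 0.15
    choice_sd_intercept: float = 0.30
    choice_sd_slope: float = 0.05

    estimate_intercept: float = 0.55
    estimate_payoff_coupling: float = 0.08
    estimate_time_trend: float = -0.35
    # occasion-indexed shifts applied only to girls: dip at the 2nd
    # estimate, spike at the 4th
    female_volatility: tuple[float, ...] = (0.0, -0.9, 0.0, 1.2)
    less_cut: float = -0.85
    more_cut: float = 0.25
    dont_know_rate: float = 0.08

    def __post_init__(self):
        if not 0.0 <= self.dont_know_rate <= 1.0:
            raise ValueError("dont_know_rate must be a probability")
        if self.less_cut >= self.more_cut:
            raise ValueError("less_cut must be below more_cut")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition. Defaults mirror the study sample: 58 valid
    participants, 29 per experimental arm, 27 girls, 16 children aged
    5y0m or older."""

    n_participants: int = 58
    n_intervention: int = 29
    n_control: int = 29
    n_female: int = 27
    n_older: int = 16
    seed: int = 0
    agent_params: AgentParams = field(default_factory=AgentParams)
    game: GameConfig = field(default_factory=GameConfig)

    def __post_init__(self):
        if self.n_intervention + self.n_control != self.n_participants:
            raise InvalidConfigError("per-arm counts must sum to n_participants")
        if max(self.n_female, self.n_older) > self.n_participants:
            raise InvalidConfigError("subgroup counts cannot exceed n_participants")
        if min(self.n_participants, self.n_intervention, self.n_control) < 0:
            raise InvalidConfigError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Generating coefficients stored alongside every synthetic cohort."""

    kind: str  # "agents" or a model-outcome name
    betas: dict[str, float] = field(default_factory=dict)
    tau0_sq: float | None = None
    tau1_sq: float | None = None
    sigma_sq: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def allocate_arms(n: int, seed: int) -> np.ndarray:
    """Balanced permuted arm allocation: floor(n/2) controls and
    ceil(n/2) intervention labels, order shuffled by ``seed``."""
    if n < 2:
        raise ValueError("allocation requires n >= 2")
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return labels


def _assign_covariates(config: CohortConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    arm = np.array([1] * config.n_intervention + [0] * config.n_control)
    rng.shuffle(arm)
    female = np.zeros(n, dtype=int)
    female[rng.choice(n, size=config.n_female, replace=False)] = 1
    older = np.zeros(n, dtype=int)
    older[rng.choice(n, size=config.n_older, replace=False)] = 1
    # months: younger children 3y0m-4y11m, older 5y0m-6y6m
    age_months = np.where(
        older == 1, rng.integers(60, 79, size=n), rng.integers(36, 60, size=n)
    )
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
            "arm": arm,
            "female": female,
            "age_months": age_months,
            "age_group": older,
        }
    )


def draw_estimate_category(
    params: AgentParams,
    rng: np.random.Generator,
    occasion: int,
    payoff_change: float,
    female: int,
) -> str:
    """Sample one estimate category from the ordered-threshold policy.

    Latent optimism rises with the last payoff change and falls over
    occasions; girls additionally carry the occasion-indexed
    volatility shift. DONT_KNOW occurs with ``dont_know_rate``
    independently of the latent scale.
    """
    if rng.random() < params.dont_know_rate:
        return DONT_KNOW
    shift = (
        params.female_volatility[occasion - 1] * female
        if occasion - 1 < len(params.female_volatility)
        else 0.0
    )
    optimism = (
        params.estimate_intercept
        + params.estimate_payoff_coupling * payoff_change
        + params.estimate_time_trend * occasion
        + shift
        + rng.normal()
    )
    if optimism > params.more_cut:
        return MORE
    if optimism < params.less_cut:
        return LESS
    return SAME


def simulate_participant(
    covariates: dict,
    params: AgentParams,
    game: GameConfig,
    seed: int,
) -> ParticipantSession:
    """Simulate one child's session under the behavioral policies.

    Estimates never influence deck choices, so the session is played
    in two deterministic passes on one seeded RNG stream: choices
    first, then estimate categories computed from the finished blocks'
    realized payoffs.
    """
    rng = np.random.default_rng(seed)
    u0 = rng.normal(0.0, params.choice_sd_intercept)
    u1 = rng.normal(0.0, params.choice_sd_slope)
    female = int(covariates["female"])
    age_group = int(covariates["age_group"])
    arm = int(covariates["arm"])

    def choose(turn_index, block_index, state):
        post = int(block_index > INTERVENTION_AFTER_BLOCK)
        eta = (
            params.choice_intercept
            + params.choice_trend * block_index
            + params.choice_female * female
            + params.choice_age * age_group
            + params.choice_intervention_post * arm * post
            + u0
            + u1 * block_index
        )
        return SAFE if rng.random() < ndtr(eta) else RISKY

    session = run_session(
        choice_source=choose,
        estimate_source=lambda occ, ref: SAME,  # pass 1: choices only
        config=game,
        participant_id=str(covariates.get("participant_id", "P000")),
        arm=arm,
        female=female,
        age_months=int(covariates.get("age_months", 54)),
        age_group=age_group,
    )
    payoffs = [b.block_payoff for b in session.blocks]

    def change_before(reference_block: int) -> int:
        prev = payoffs[reference_block - 2] if reference_block >= 2 else 0
        return payoffs[reference_block - 1] - prev

    session.estimates = [
        EstimateRecord(
            occasion=e.occasion,
            category=draw_estimate_category(
                params, rng, e.occasion, change_before(e.reference_block), female
            ),
            reference_block=e.reference_block,
            target_block=e.target_block,
        )
        for e in session.estimates
    ]
    return session


def simulate_cohort(config: CohortConfig | None = None) -> tuple[Cohort, GroundTruth]:
    """Simulate a full behavioral cohort; returns (cohort, ground truth)."""
    if config is None:
        config = CohortConfig()
    cov = _assign_covariates(config)
    sessions = []
    for i, row in cov.iterrows():
        sessions.append(
            simulate_participant(
                row.to_dict(),
                config.agent_params,
                config.game,
                seed=int(np.random.default_rng((config.seed, 1, i)).integers(2**31)),
            )
        )
    truth = GroundTruth(
        kind="agents",
        betas={
            "choice_intercept": config.agent_params.choice_intercept,
            "choice_trend": config.agent_params.choice_trend,
            "choice_female": config.agent_params.choice_female,
            "choice_age": config.agent_params.choice_age,
            "choice_intervention_post": config.agent_params.choice_intervention_post,
            "estimate_intercept": config.agent_params.estimate_intercept,
            "estimate_payoff_coupling": config.agent_params.estimate_payoff_coupling,
            "estimate_time_trend": config.agent_params.estimate_time_trend,
        },
        extra={"config_seed": config.seed},
    )
    return Cohort(sessions), truth


# --------------------------------------------------------------------------
# Model-based outcome generator (for parameter recovery)
# --------------------------------------------------------------------------

#: Default generating fixed effects for recovery experiments, chosen in
#: the effect-size regime the analysis targets.
DEFAULT_GROUND_TRUTH: dict[str, GroundTruth] = {
    "relative_safe": GroundTruth(
        kind="relative_safe",
        betas={
            "intervention": 0.053, "age_group": 0.037, "female": 0.117,
            "time": 0.025, "intervention:age_group:time": 0.001,
            "intercept": 0.196,
        },
        tau0_sq=0.014, tau1_sq=0.003, sigma_sq=0.040,
    ),
    "payoffs": GroundTruth(
        kind="payoffs",
        betas={
            "intervention": 1.969, "age_group": 0.145, "female": 2.867,
            "time": 0.080, "intervention:age_group:time": -0.001,
            "intercept": -1.801,
        },
        tau0_sq=0.892, tau1_sq=0.042, sigma_sq=17.413,
    ),
    "overconfidence": GroundTruth(
        kind="overconfidence",
        betas={
            "intervention": -0.111, "age_group": -0.221, "female": -0.303,
            "time": -0.585, "female:occ2": -0.758, "female:occ4": 1.042,
            "intercept": 2.412,
        },
        tau0_sq=0.358, tau1_sq=0.151,
    ),
}


def covariate_frame(
    config: CohortConfig | None = None, n_times: int = 6
) -> pd.DataFrame:
    """Long covariate layout (participant x time) without outcomes."""
    if config is None:
        config = CohortConfig()
    cov = _assign_covariates(config)
    rows = []
    for _, r in cov.iterrows():
        for time in range(1, n_times + 1):
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "intervention": int(r["arm"]),
                    "female": int(r["female"]),
                    "age_group": int(r["age_group"]),
                    "time": time,
                }
            )
    return pd.DataFrame(rows)


def simulate_outcome_table(
    outcome: str,
    truth: GroundTruth | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a long outcome table directly from the mixed model.

    ``outcome`` is one of ``relative_safe``, ``payoffs``,
    ``overconfidence``. Random effects are N(0, tau^2), residuals
    N(0, sigma^2) for linear outcomes; the probit outcome is Bernoulli
    with probability Phi(eta). Returns (table, ground truth used).
    """
    if outcome not in MODEL_SPECS:
        raise InvalidConfigError(f"unknown outcome {outcome!r}")
    spec: ModelSpec = MODEL_SPECS[outcome]()
    if truth is None:
        truth = DEFAULT_GROUND_TRUTH[outcome]
    if config is None:
        config = CohortConfig(seed=seed)
    n_times = 4 if spec.link == PROBIT else 6
    table = covariate_frame(config, n_times=n_times)
    col = spec.outcome
    table[col] = 0.0  # placeholder so build_design can read the frame
    X, names, _, groups, t, ids = build_design(table, spec)
    beta = np.array([truth.betas[name] for name in names])
    rng = np.random.default_rng(seed)
    m = len(ids)
    u0 = rng.normal(0.0, np.sqrt(truth.tau0_sq), size=m)
    u1 = rng.normal(0.0, np.sqrt(truth.tau1_sq), size=m)
    eta = X @ beta + u0[groups] + u1[groups] * t
    if spec.link == PROBIT:
        y = (rng.random(len(eta)) < ndtr(eta)).astype(int)
    else:
        y = eta + rng.normal(0.0, np.sqrt(truth.sigma_sq), size=len(eta))
    table[col] = y
    return table, truth
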