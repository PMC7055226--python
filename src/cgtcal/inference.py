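"""Bayesian random-intercept + random-slope mixed models via Gibbs sampling.

Three models share one longitudinal structure: participant ``i`` is
observed at times ``t`` (blocks 1-6 for the linear outcomes, estimate
occasions 1-4 for the binary one), with

    eta_it = x_it' beta + u_i0 + u_i1 * t

* **Linear mixed model** (relative safe-card selection; block payoffs;
  the miscalibration robustness check): ``y_it = eta_it + eps_it``,
  ``eps ~ N(0, sigma^2)``.
* **Probit mixed model** (binary overconfidence):
  ``P(y_it = 1) = Phi(eta_it)``, sampled by latent-variable
  augmentation: a truncated-normal latent response ``z_it ~ N(eta_it,
  1)`` constrained to the sign implied by ``y_it`` turns every
  conditional conjugate (Albert-Chib scheme).

Priors: independent ``N(0, 10^4)`` on each fixed effect (a near-flat
"null effect" default), inverse-gamma(0.01, 0.01) on the residual
variance sigma^2 and the random-effect variances tau0^2 (intercepts)
and tau1^2 (slopes). Random intercept and slope are a priori
independent (diagonal covariance). All priors are configurable.

Every conditional is conjugate, so the sampler is a pure Gibbs scan:

1. beta | rest  ~ MVN from the weighted least-squares posterior,
2. u_i0, u_i1 | rest ~ independent normals per participant,
3. variances | rest ~ inverse-gamma,
4. (probit only) z | rest ~ truncated normals.

Chains are seeded ``seed + chain_index`` and are independent of
execution order. Posterior summaries follow the Bayesian-estimation
reporting style: posterior mean (pM), posterior SD (pSD), 95% highest
posterior density (HPD) interval, mass inside a region of practical
equivalence (ROPE), and the Gelman-Rubin potential scale reduction
factor (PSRF).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import (
    DegenerateChainsError,
    InsufficientDrawsError,
    NonBinaryOutcomeError,
    RankDeficientDesignError,
)

logger = logging.getLogger("cgtcal")

IDENTITY = "identity"
PROBIT = "probit"


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed- and random-effect layout for one outcome.

    ``fixed_terms`` are design-column names drawn from: ``intervention``,
    ``age_group``, ``female``, ``time``, the three-way
    ``intervention:age_group:time`` product, the occasion dummies
    ``female:occ2`` / ``female:occ4``, and ``intercept``. Each term maps
    to exactly one design column; no general formula language is
    provided. Random terms are always a per-participant intercept and
    slope on ``time``.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    link: str = IDENTITY

    def __post_init__(self):
        if self.link not in (IDENTITY, PROBIT):
            raise ValueError(f"unknown link {self.link!r}")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")


#: Display labels for design columns, in report order.
TERM_LABELS = {
    "intervention": "Intervention",
    "age_group": "Age",
    "female": "Female",
    "time": "Time",
    "intervention:age_group:time": "Intervention x Age x Time",
    "female:occ2": "Female, 2nd Estimate",
    "female:occ4": "Female, 4th Estimate",
    "intercept": "Constant",
}

_LINEAR_TERMS = (
    "intervention",
    "age_group",
    "female",
    "time",
    "intervention:age_group:time",
    "intercept",
)
_PROBIT_TERMS = (
    "intervention",
    "age_group",
    "female",
    "time",
    "female:occ2",
    "female:occ4",
    "intercept",
)


def relative_safe_spec() -> ModelSpec:
    """Linear mixed model for per-block relative safe-card selection."""
    return ModelSpec("relative_safe", _LINEAR_TERMS, IDENTITY)


def payoff_spec() -> ModelSpec:
    """Linear mixed model for per-block sticker payoffs."""
    return ModelSpec("payoff", _LINEAR_TERMS, IDENTITY)


def overconfidence_spec() -> ModelSpec:
    """Probit mixed model for the binary per-occasion overconfidence score."""
    return ModelSpec("overconfidence", _PROBIT_TERMS, PROBIT)


def miscalibration_spec() -> ModelSpec:
    """Robustness check: trinary miscalibration as a linear-model outcome."""
    return ModelSpec("miscalibration", _PROBIT_TERMS, IDENTITY)


MODEL_SPECS = {
    "relative_safe": relative_safe_spec,
    "payoffs": payoff_spec,
    "overconfidence": overconfidence_spec,
    "miscalibration": miscalibration_spec,
}


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate prior settings.

    fixed_effect_variance is the prior variance of each beta (mean
    ``fixed_effect_mean``); the inverse-gamma (shape, scale) pair
    applies to sigma^2, tau0^2 and tau1^2 alike.
    """

    fixed_effect_mean: float = 0.0
    fixed_effect_variance: float = 10_000.0
    variance_shape: float = 0.01
    variance_scale: float = 0.01

    def __post_init__(self):
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be positive")
        if self.variance_shape <= 0 or self.variance_scale <= 0:
            raise ValueError("inverse-gamma parameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout. ``n_iterations`` counts monitored (post burn-in)
    iterations; ``n_iterations / thinning`` draws per chain are kept."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_iterations: int = 100_000
    thinning: int = 5
    seed: int = 12345

    def __post_init__(self):
        if min(self.n_chains, self.burn_in, self.n_iterations, self.thinning) < 1:
            raise ValueError("all MCMC settings must be positive")
        if self.n_iterations % self.thinning:
            raise ValueError("n_iterations must be divisible by thinning")

    @property
    def kept_per_chain(self) -> int:
        return self.n_iterations // self.thinning


def default_linear_mcmc(**kw) -> MCMCConfig:
    """Study defaults for the linear models: 2 chains, burn 10k, 100k
    monitored, thinning 5, seed 12345."""
    return MCMCConfig(**{**dict(n_chains=2, burn_in=10_000, n_iterations=100_000,
                                thinning=5, seed=12345), **kw})


def default_probit_mcmc(**kw) -> MCMCConfig:
    """Study defaults for the probit model: 2 chains, burn 10k, 400k
    monitored, thinning 20, seed 1234."""
    return MCMCConfig(**{**dict(n_chains=2, burn_in=10_000, n_iterations=400_000,
                                thinning=20, seed=1234), **kw})


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------


def build_design(table: pd.DataFrame, spec: ModelSpec):
    """Long table -> (X, names, y, group index, time vector).

    ``time`` is used untransformed (no centering or standardization):
    blocks 1-6 or occasions 1-4.
    """
    n = len(table)
    t = table["time"].to_numpy(dtype=float)
    cols = {}
    for term in spec.fixed_terms:
        if term == "intercept":
            cols[term] = np.ones(n)
        elif term == "intervention:age_group:time":
            cols[term] = (
                table["intervention"].to_numpy(float)
                * table["age_group"].to_numpy(float)
                * t
            )
        elif term == "female:occ2":
            cols[term] = table["female"].to_numpy(float) * (t == 2)
        elif term == "female:occ4":
            cols[term] = table["female"].to_numpy(float) * (t == 4)
        elif term == "time":
            cols[term] = t
        else:
            cols[term] = table[term].to_numpy(dtype=float)
    X = np.column_stack([cols[term] for term in spec.fixed_terms])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            f"collinear fixed terms in design for outcome {spec.outcome!r}"
        )
    y = table[spec.outcome].to_numpy(dtype=float)
    ids, groups = np.unique(table["participant_id"].to_numpy(), return_inverse=True)
    return X, list(spec.fixed_terms), y, groups, t, list(ids)


def _detect_separation(X: np.ndarray, names: list[str], y: np.ndarray) -> None:
    # complete separation by a single binary column: warn, let priors regularize
    for j, name in enumerate(names):
        col = X[:, j]
        vals = np.unique(col)
        if name == "intercept" or len(vals) != 2:
            continue
        hi, lo = col == vals.max(), col == vals.min()
        if hi.any() and lo.any():
            if (y[hi].min() > y[lo].max()) or (y[lo].min() > y[hi].max()):
                logger.warning(
                    "complete separation detected on term %r; "
                    "sampling proceeds, priors regularize", name
                )


# --------------------------------------------------------------------------
# Posterior draws container
# --------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Monitored, thinned MCMC draws for every model parameter.

    ``draws[name]`` has shape ``(n_chains, n_kept)``. Parameter order
    is fixed effects (in spec order), then random-effect variances
    ``tau0_sq``/``tau1_sq``, then (linear models) ``sigma_sq``;
    per-participant effects are stored as ``u0[<id>]``/``u1[<id>]`` and
    excluded from the default summary order.
    """

    draws: dict[str, np.ndarray]
    param_order: list[str]
    spec: ModelSpec
    mcmc: MCMCConfig
    participant_ids: list = field(default_factory=list)

    def __post_init__(self):
        for name, arr in self.draws.items():
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite draws for {name}")

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)

    def pM(self, name: str) -> float:
        return float(self.stacked(name).mean())

    def pSD(self, name: str) -> float:
        return float(self.stacked(name).std(ddof=1))

    def hpd(self, name: str, level: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.stacked(name), level)

    def rope(self, name: str, center: float = 0.0, half_width: float = 0.1) -> float:
        return rope_mass(self.stacked(name), center, half_width)

    def psrf(self, name: str) -> float:
        return psrf(self.draws[name])

    def to_dataframe(self) -> pd.DataFrame:
        """Draws in long-ish form: chain, iteration, one column per parameter."""
        n_chains, n_kept = next(iter(self.draws.values())).shape
        out = {
            "chain": np.repeat(np.arange(n_chains), n_kept),
            "iteration": np.tile(np.arange(n_kept), n_chains),
        }
        for name in self.draws:
            out[name] = self.draws[name].reshape(-1)
        return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Gibbs samplers
# --------------------------------------------------------------------------


def _gibbs_chain(
    X, y_obs, groups, t, link, priors, n_total, keep_idx, rng,
    include_random=True, fix_sigma2=None,
):
    """One chain of the shared Gibbs scan; returns dict of kept draws."""
    n, p = X.shape
    m = int(groups.max()) + 1 if include_random else 0
    XtX = X.T @ X
    b0 = priors.fixed_effect_mean
    B0_inv = np.eye(p) / priors.fixed_effect_variance
    a_v, b_v = priors.variance_shape, priors.variance_scale
    probit = link == PROBIT

    # per-group aggregation helpers
    if include_random:
        n_i = np.bincount(groups, minlength=m).astype(float)
        t_sq_i = np.bincount(groups, weights=t * t, minlength=m)

    beta = np.zeros(p)
    u0 = np.zeros(m)
    u1 = np.zeros(m)
    tau0_sq = 1.0
    tau1_sq = 1.0
    sigma_sq = 1.0 if (probit or fix_sigma2 is not None) else float(np.var(y_obs) or 1.0)
    if fix_sigma2 is not None:
        sigma_sq = float(fix_sigma2)
    z = y_obs.astype(float).copy()
    if probit:
        z = np.where(y_obs > 0, 0.5, -0.5)  # latent init on the correct side

    n_keep = len(keep_idx)
    out_beta = np.empty((n_keep, p))
    out_var = np.empty((n_keep, 3))  # tau0_sq, tau1_sq, sigma_sq
    out_u = np.empty((n_keep, 2, m)) if include_random else None
    keep_set = keep_idx
    k = 0
    tiny = 1e-300

    for it in range(n_total):
        re_part = (u0[groups] + u1[groups] * t) if include_random else 0.0

        if probit:
            # z | rest ~ N(eta, 1) truncated to the sign of y
            eta = X @ beta + re_part
            lo = np.where(y_obs > 0, ndtr(-eta), 0.0)
            hi = np.where(y_obs > 0, 1.0, ndtr(-eta))
            u_unif = lo + (hi - lo) * rng.random(n)
            z = eta + ndtri(np.clip(u_unif, 1e-15, 1 - 1e-15))
            y_work = z
        else:
            y_work = z  # == y_obs for linear models

        # beta | rest
        resid_target = y_work - re_part
        V_inv = XtX / sigma_sq + B0_inv
        L = np.linalg.cholesky(V_inv)
        rhs = X.T @ resid_target / sigma_sq + B0_inv @ (b0 * np.ones(p))
        w = np.linalg.solve(L, rhs)
        mean = np.linalg.solve(L.T, w)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        fixed_part = X @ beta

        if include_random:
            # u_i0 | rest
            r0 = y_work - fixed_part - u1[groups] * t
            prec0 = n_i / sigma_sq + 1.0 / tau0_sq
            mean0 = np.bincount(groups, weights=r0, minlength=m) / sigma_sq / prec0
            u0 = mean0 + rng.standard_normal(m) / np.sqrt(prec0)
            # u_i1 | rest
            r1 = y_work - fixed_part - u0[groups]
            prec1 = t_sq_i / sigma_sq + 1.0 / tau1_sq
            mean1 = np.bincount(groups, weights=r1 * t, minlength=m) / sigma_sq / prec1
            u1 = mean1 + rng.standard_normal(m) / np.sqrt(prec1)
            # tau^2 | rest
            tau0_sq = 1.0 / rng.gamma(a_v + m / 2.0, 1.0 / (b_v + 0.5 * u0 @ u0 + tiny))
            tau1_sq = 1.0 / rng.gamma(a_v + m / 2.0, 1.0 / (b_v + 0.5 * u1 @ u1 + tiny))
            re_part = u0[groups] + u1[groups] * t

        if not probit and fix_sigma2 is None:
            resid = y_work - fixed_part - (re_part if include_random else 0.0)
            sigma_sq = 1.0 / rng.gamma(
                a_v + n / 2.0, 1.0 / (b_v + 0.5 * resid @ resid + tiny)
            )

        if k < n_keep and it == keep_set[k]:
            out_beta[k] = beta
            out_var[k] = (tau0_sq, tau1_sq, sigma_sq)
            if include_random:
                out_u[k, 0] = u0
                out_u[k, 1] = u1
            k += 1

    return out_beta, out_var, out_u


def _run_model(
    table, spec, priors, mcmc, include_random=True, fix_sigma2=None
) -> PosteriorDraws:
    X, names, y, groups, t, ids = build_design(table, spec)
    probit = spec.link == PROBIT
    if probit:
        uniq = np.unique(y)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise NonBinaryOutcomeError(
                f"probit outcome must be 0/1, found values {uniq}"
            )
        _detect_separation(X, names, y)

    n_total = mcmc.burn_in + mcmc.n_iterations
    keep_idx = np.arange(
        mcmc.burn_in + mcmc.thinning - 1, n_total, mcmc.thinning
    )
    chains_beta, chains_var, chains_u = [], [], []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(mcmc.seed + c)
        ob, ov, ou = _gibbs_chain(
            X, y, groups, t, spec.link, priors, n_total, keep_idx, rng,
            include_random=include_random, fix_sigma2=fix_sigma2,
        )
        chains_beta.append(ob)
        chains_var.append(ov)
        chains_u.append(ou)

    draws: dict[str, np.ndarray] = {}
    order: list[str] = []
    for j, name in enumerate(names):
        draws[name] = np.stack([cb[:, j] for cb in chains_beta])
        order.append(name)
    if include_random:
        draws["tau0_sq"] = np.stack([cv[:, 0] for cv in chains_var])
        draws["tau1_sq"] = np.stack([cv[:, 1] for cv in chains_var])
        order += ["tau0_sq", "tau1_sq"]
    if spec.link == IDENTITY and fix_sigma2 is None:
        draws["sigma_sq"] = np.stack([cv[:, 2] for cv in chains_var])
        order.append("sigma_sq")
    if include_random:
        for gi, pid in enumerate(ids):
            draws[f"u0[{pid}]"] = np.stack([cu[:, 0, gi] for cu in chains_u])
            draws[f"u1[{pid}]"] = np.stack([cu[:, 1, gi] for cu in chains_u])
    return PosteriorDraws(draws, order, spec, mcmc, ids)


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    include_random: bool = True,
    fix_sigma2: float | None = None,
) -> PosteriorDraws:
    """Fit a Bayesian random-slope linear mixed model by Gibbs sampling.

    ``include_random=False`` and ``fix_sigma2`` exist for validation
    against the closed-form normal posterior: with random effects
    disabled and sigma^2 fixed, successive beta draws are exact
    independent samples from N(V X'y / sigma^2, V),
    V = (X'X / sigma^2 + B0^-1)^-1.
    """
    if spec.link != IDENTITY:
        raise ValueError("fit_lmm requires an identity link; use fit_probit_glmm")
    return _run_model(
        table, spec, priors or PriorSpec(), mcmc or default_linear_mcmc(),
        include_random=include_random, fix_sigma2=fix_sigma2,
    )


def fit_probit_glmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    include_random: bool = True,
) -> PosteriorDraws:
    """Fit the Bayesian random-slope probit mixed model.

    Latent-variable augmentation: truncated-normal latent responses
    given the outcome sign, then the conjugate normal/inverse-gamma
    updates of the linear sampler with the latent residual variance
    fixed at 1.
    """
    if spec.link != PROBIT:
        raise ValueError("fit_probit_glmm requires a probit link")
    return _run_model(
        table, spec, priors or PriorSpec(), mcmc or default_probit_mcmc(),
        include_random=include_random, fix_sigma2=None,
    )


# --------------------------------------------------------------------------
# Posterior summaries
# --------------------------------------------------------------------------


def hpd_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(level * n)`` draws.

    Unlike an equal-tail credible interval, the HPD interval is the
    minimal-width window of the sorted draws; ties on width resolve to
    the leftmost window (deterministic).
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise InsufficientDrawsError(f"HPD needs >= 100 draws, got {n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    k = math.ceil(level * n)
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(x[j]), float(x[j + k - 1])


def rope_mass(draws, center: float = 0.0, half_width: float = 0.1) -> float:
    """Fraction of draws inside [center - half_width, center + half_width] (inclusive)."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    x = np.asarray(draws, dtype=float)
    return float(np.mean(np.abs(x - center) <= half_width))


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B the between-chain variance component. A single
    chain is split in half.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    if arr.shape[0] == 1:
        n = arr.shape[1]
        if n < 20:
            raise InsufficientDrawsError("split-chain PSRF needs >= 20 draws")
        half = n // 2
        arr = np.stack([arr[0, :half], arr[0, half: 2 * half]])
    m, n = arr.shape
    if n < 10:
        raise InsufficientDrawsError("PSRF needs chains of length >= 10")
    within = arr.var(axis=1, ddof=1)
    W = within.mean()
    if W <= 0:
        raise DegenerateChainsError("zero within-chain variance")
    B = n * arr.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


_VARIANCE_LABELS = {
    "tau0_sq": "Random Intercept",
    "tau1_sq": "Random Slope",
    "sigma_sq": "Residual Variance",
}


def summarize(
    draws: PosteriorDraws,
    rope_half_width: float = 0.1,
    rope_center: float = 0.0,
    hpd_level: float = 0.95,
    as_percent: bool = False,
) -> pd.DataFrame:
    """One summary row per parameter: pM, pSD, HPD, ROPE masses, PSRF.

    Row order is fixed effects in specification order (Intervention,
    Age, Female, Time, interaction terms, Constant), then the random
    intercept and slope variances, then (linear models) the residual
    variance. ``rope_mass_above`` is the complementary posterior mass
    above the ROPE's upper edge. With ``as_percent`` the location/scale
    columns are multiplied by 100 for display — probit coefficients are
    conventionally quoted in percent; the underlying draws stay on the
    probit scale.
    """
    rows = []
    scale = 100.0 if as_percent else 1.0
    for name in draws.param_order:
        x = draws.stacked(name)
        lo, hi = hpd_interval(x, hpd_level)
        is_variance = name in _VARIANCE_LABELS
        rows.append(
            {
                "parameter": TERM_LABELS.get(name, _VARIANCE_LABELS.get(name, name)),
                "pM": x.mean() * scale,
                "pSD": x.std(ddof=1) * scale,
                "hpd_low": lo * scale,
                "hpd_high": hi * scale,
                "rope_mass": np.nan
                if is_variance
                else rope_mass(x, rope_center, rope_half_width),
                "rope_mass_above": np.nan
                if is_variance
                else float(np.mean(x > rope_center + rope_half_width)),
                "psrf": draws.psrf(name),
            }
        )
    return pd.DataFrame(rows)


def render_summary(summary: pd.DataFrame, title: str = "") -> str:
    """Aligned plain-text rendering of a summary table."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    header = f"{'Parameter':<28}{'pM':>10}{'pSD':>10}{'95% HPD':>22}{'ROPE':>8}{'PSRF':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in summary.iterrows():
        rope = "" if np.isnan(r["rope_mass"]) else f"{r['rope_mass']:.4f}"
        lines.append(
            f"{r['parameter']:<28}{r['pM']:>10.3f}{r['pSD']:>10.3f}"
            f"{'[' + format(r['hpd_low'], '.3f') + '; ' + format(r['hpd_high'], '.3f') + ']':>22}"
            f"{rope:>8}{r['psrf']:>8.4f}"
        )
    return "\n".join(lines)
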