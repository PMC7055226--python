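"""Sampler correctness against independent oracles; posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

from cgtcal import (
    MCMCConfig,
    ModelSpec,
    PriorSpec,
    fit_lmm,
    fit_probit_glmm,
    hpd_interval,
    overconfidence_spec,
    payoff_spec,
    psrf,
    rope_mass,
    simulate_outcome_table,
    summarize,
)
from cgtcal.errors import (
    DegenerateChainsError,
    InsufficientDrawsError,
    NonBinaryOutcomeError,
    RankDeficientDesignError,
)
from cgtcal.inference import IDENTITY, PROBIT, TERM_LABELS


def _toy_table(y, x=None, n_per_group=1):
    n = len(y)
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i // n_per_group:03d}" for i in range(n)],
            "time": (np.arange(n) % 4) + 1,
            "y": y,
        }
    )
    if x is not None:
        df["x"] = x
    return df


# ---------------------------------------------------------------------------
# HPD
# ---------------------------------------------------------------------------


def hpd_scan_oracle(draws, level):
    """Brute-force shortest-window scan over the sorted draws."""
    x = np.sort(draws)
    n = len(x)
    k = int(np.ceil(level * n))
    best = (np.inf, None)
    for j in range(n - k + 1):
        width = x[j + k - 1] - x[j]
        if width < best[0]:
            best = (width, j)
    j = best[1]
    return x[j], x[j + k - 1]


def test_hpd_constant_draws():
    assert hpd_interval(np.full(500, 3.25)) == (3.25, 3.25)


def test_hpd_matches_scan_oracle_on_seeded_draws():
    rng = np.random.default_rng(20240)
    draws = rng.standard_normal(100_000)
    assert hpd_interval(draws, 0.95) == pytest.approx(
        hpd_scan_oracle(draws, 0.95), abs=0
    )
    # mixture posterior, same check at another level
    draws2 = np.concatenate([rng.normal(-2, 0.5, 5_000), rng.normal(1, 1, 15_000)])
    assert hpd_interval(draws2, 0.9) == pytest.approx(
        hpd_scan_oracle(draws2, 0.9), abs=0
    )


def test_hpd_shorter_than_equal_tail_on_skewed_draws():
    rng = np.random.default_rng(7)
    draws = rng.exponential(size=50_000)
    lo, hi = hpd_interval(draws, 0.95)
    q_lo, q_hi = np.quantile(draws, [0.025, 0.975])
    assert lo < q_lo  # HPD hugs the mode of the right-skewed density
    assert hi - lo < q_hi - q_lo


def test_hpd_agrees_with_arviz_hdi():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(11)
    draws = rng.gamma(3.0, size=20_000)
    lo, hi = hpd_interval(draws, 0.94)
    ref = az.hdi(draws, hdi_prob=0.94)
    # conventions differ by one draw in the window count (ceil here,
    # floor in arviz), so endpoints agree only up to order-statistic
    # spacing, ~1/(n * density) near the endpoints
    assert (lo, hi) == pytest.approx(tuple(ref), abs=0.03)


def test_hpd_requires_enough_draws():
    with pytest.raises(InsufficientDrawsError):
        hpd_interval(np.zeros(50))


# ---------------------------------------------------------------------------
# ROPE
# ---------------------------------------------------------------------------


def test_rope_degenerate_masses():
    assert rope_mass(np.zeros(1000), 0.0, 0.01) == 1.0
    assert rope_mass(np.full(1000, 5.0), 0.0, 0.01) == 0.0


def test_rope_matches_normal_cdf_closed_form():
    rng = np.random.default_rng(2024)
    draws = rng.standard_normal(400_000)
    expected = 2 * stats.norm.cdf(0.5) - 1  # ~0.3829
    assert rope_mass(draws, 0.0, 0.5) == pytest.approx(expected, abs=0.01)


def test_rope_and_complement_sum_to_one():
    rng = np.random.default_rng(3)
    draws = rng.normal(0.2, 1.0, 10_000)
    inside = rope_mass(draws, 0.0, 0.1)
    outside = np.mean(np.abs(draws) > 0.1)
    assert inside + outside == pytest.approx(1.0, abs=0)


# ---------------------------------------------------------------------------
# PSRF
# ---------------------------------------------------------------------------


def test_psrf_matches_formula_oracle():
    rng = np.random.default_rng(5)
    chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    expected = np.sqrt(((n - 1) / n * W + B / n) / W)
    assert psrf(chains) == pytest.approx(expected, abs=1e-10)
    assert psrf(chains) > 2  # far-apart chains are flagged


def test_psrf_near_one_for_iid_chains():
    rng = np.random.default_rng(8)
    chains = rng.standard_normal((2, 50_000))
    assert psrf(chains) <= 1.01


def test_psrf_single_chain_split_mode():
    rng = np.random.default_rng(9)
    assert psrf(rng.standard_normal(10_000)) == pytest.approx(1.0, abs=0.01)


def test_psrf_degenerate_chains():
    with pytest.raises(DegenerateChainsError):
        psrf(np.zeros((2, 100)))


# ---------------------------------------------------------------------------
# Linear sampler vs conjugate closed form
# ---------------------------------------------------------------------------


def closed_form_posterior(X, y, sigma2, prior_var):
    """Exact normal posterior for beta with fixed sigma^2, flat-ish prior."""
    V = np.linalg.inv(X.T @ X / sigma2 + np.eye(X.shape[1]) / prior_var)
    mean = V @ (X.T @ y / sigma2)
    return mean, V


def test_lmm_matches_conjugate_closed_form():
    """Fixed-variance, no-random-effects fit: draws are exact samples
    from the known normal posterior; compare within 3 Monte-Carlo SEs."""
    rng = np.random.default_rng(77)
    n = 120
    x = rng.standard_normal(n)
    y = 1.5 + 0.8 * x + rng.normal(0, 2.0, n)
    table = _toy_table(y, x)
    spec = ModelSpec("y", ("x", "intercept"), IDENTITY)
    sigma2, prior_var = 4.0, 10_000.0
    mc = MCMCConfig(n_chains=2, burn_in=200, n_iterations=20_000, thinning=1, seed=3)
    draws = fit_lmm(table, spec, PriorSpec(fixed_effect_variance=prior_var),
                    mc, include_random=False, fix_sigma2=sigma2)
    X = np.column_stack([x, np.ones(n)])
    mean, V = closed_form_posterior(X, y, sigma2, prior_var)
    n_draws = mc.n_chains * mc.kept_per_chain
    for j, name in enumerate(["x", "intercept"]):
        mcse = np.sqrt(V[j, j] / n_draws)  # draws are iid here
        assert abs(draws.pM(name) - mean[j]) < 3 * mcse
        assert draws.pSD(name) == pytest.approx(np.sqrt(V[j, j]), rel=0.05)


def test_lmm_all_zero_outcome_centers_on_zero():
    rng = np.random.default_rng(10)
    table = _toy_table(np.zeros(40), rng.standard_normal(40))
    spec = ModelSpec("y", ("x", "intercept"), IDENTITY)
    mc = MCMCConfig(n_chains=2, burn_in=200, n_iterations=5_000, thinning=1, seed=4)
    draws = fit_lmm(table, spec, mcmc=mc, include_random=False, fix_sigma2=1.0)
    for name in ("x", "intercept"):
        n_draws = mc.n_chains * mc.kept_per_chain
        mcse = draws.pSD(name) / np.sqrt(n_draws)
        assert abs(draws.pM(name)) < 3 * mcse + 1e-6


def test_lmm_reproducible_bitwise():
    table, _ = simulate_outcome_table("payoffs", seed=2)
    mc = MCMCConfig(n_chains=2, burn_in=50, n_iterations=200, thinning=1, seed=9)
    d1 = fit_lmm(table, payoff_spec(), mcmc=mc)
    d2 = fit_lmm(table, payoff_spec(), mcmc=mc)
    for name in d1.param_order:
        assert np.array_equal(d1.draws[name], d2.draws[name])


def test_rank_deficient_design_rejected():
    table, _ = simulate_outcome_table("payoffs", seed=2)
    table["dup"] = table["female"]
    spec = ModelSpec("payoff", ("female", "dup", "intercept"), IDENTITY)
    with pytest.raises(RankDeficientDesignError):
        fit_lmm(table, spec)


# ---------------------------------------------------------------------------
# Probit sampler
# ---------------------------------------------------------------------------


def test_probit_rejects_non_binary_outcome():
    table = _toy_table(np.array([0, 1, 2, 0]))
    with pytest.raises(NonBinaryOutcomeError):
        fit_probit_glmm(table, ModelSpec("y", ("intercept",), PROBIT))


def test_probit_intercept_sign_with_all_zero_outcomes():
    """With 50 failures and no successes the intercept must be negative."""
    table = _toy_table(np.zeros(50, dtype=int))
    mc = MCMCConfig(n_chains=2, burn_in=500, n_iterations=5_000, thinning=1, seed=6)
    draws = fit_probit_glmm(
        table, ModelSpec("y", ("intercept",), PROBIT),
        PriorSpec(fixed_effect_variance=100.0), mc, include_random=False,
    )
    assert np.mean(draws.stacked("intercept") < 0) > 0.99


def test_probit_large_sample_consistency():
    """n=5000, beta=(0, 1) on a standard-normal covariate, no random
    effects: posterior means land within 0.1 of the generating values."""
    rng = np.random.default_rng(123)
    n = 5_000
    x = rng.standard_normal(n)
    y = (rng.random(n) < ndtr(0.0 + 1.0 * x)).astype(int)
    table = _toy_table(y, x)
    spec = ModelSpec("y", ("intercept", "x"), PROBIT)
    mc = MCMCConfig(n_chains=2, burn_in=500, n_iterations=2_000, thinning=1, seed=1)
    draws = fit_probit_glmm(table, spec, mcmc=mc, include_random=False)
    assert abs(draws.pM("intercept") - 0.0) < 0.1
    assert abs(draws.pM("x") - 1.0) < 0.1


def metropolis_probit_oracle(X, y, prior_var, n_iter, seed, step=0.6):
    """Independent random-walk Metropolis sampler on the same posterior."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    def log_post(beta):
        eta = X @ beta
        ll = np.sum(np.where(y == 1, stats.norm.logcdf(eta), stats.norm.logcdf(-eta)))
        return ll - 0.5 * beta @ beta / prior_var

    beta = np.zeros(p)
    lp = log_post(beta)
    out = np.empty((n_iter, p))
    for it in range(n_iter):
        prop = beta + step * rng.standard_normal(p)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
        out[it] = beta
    return out[n_iter // 5:]  # drop 20% burn-in


def test_probit_gibbs_matches_metropolis_oracle():
    """10-row toy dataset: augmented Gibbs and an independent RW-MH
    sampler target the same posterior; means agree within 3 joint MCSE."""
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(55)
    x = rng.standard_normal(10)
    y = np.array([0, 1, 1, 0, 1, 0, 1, 1, 0, 1])
    table = _toy_table(y, x)
    spec = ModelSpec("y", ("intercept", "x"), PROBIT)
    prior_var = 100.0
    mc = MCMCConfig(n_chains=2, burn_in=2_000, n_iterations=40_000, thinning=2, seed=21)
    draws = fit_probit_glmm(
        table, spec, PriorSpec(fixed_effect_variance=prior_var), mc,
        include_random=False,
    )
    X = np.column_stack([np.ones(10), x])
    mh = metropolis_probit_oracle(X, y, prior_var, n_iter=120_000, seed=77)
    for j, name in enumerate(["intercept", "x"]):
        mcse_g = draws.pSD(name) / np.sqrt(float(az.ess(draws.draws[name])))
        mh_j = mh[:, j]
        mcse_m = mh_j.std(ddof=1) / np.sqrt(float(az.ess(mh_j[None, :])))
        joint = np.sqrt(mcse_g**2 + mcse_m**2)
        assert abs(draws.pM(name) - mh_j.mean()) < 3 * joint, name


def test_probit_separation_warning(caplog):
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    y = x.copy()
    table = _toy_table(y, x)
    spec = ModelSpec("y", ("x", "intercept"), PROBIT)
    mc = MCMCConfig(n_chains=1, burn_in=50, n_iterations=200, thinning=1, seed=2)
    with caplog.at_level("WARNING", logger="cgtcal"):
        fit_probit_glmm(table, spec, mcmc=mc, include_random=False)
    assert any("separation" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def probit_fit(model_tables):
    mc = MCMCConfig(n_chains=2, burn_in=1_000, n_iterations=8_000, thinning=4, seed=17)
    return fit_probit_glmm(model_tables["overconfidence"], overconfidence_spec(), mcmc=mc)


def test_summary_row_order_matches_report_convention(probit_fit):
    summary = summarize(probit_fit, rope_half_width=0.1)
    assert list(summary["parameter"]) == [
        "Intervention", "Age", "Female", "Time",
        "Female, 2nd Estimate", "Female, 4th Estimate", "Constant",
        "Random Intercept", "Random Slope",
    ]
    fixed = summary[~summary["parameter"].str.startswith("Random")]
    assert ((fixed["rope_mass"] + fixed["rope_mass_above"]) <= 1 + 1e-12).all()


def test_summary_percent_scaling(probit_fit):
    plain = summarize(probit_fit, rope_half_width=0.1)
    pct = summarize(probit_fit, rope_half_width=0.1, as_percent=True)
    assert pct["pM"].to_numpy() == pytest.approx(100 * plain["pM"].to_numpy())
    # ROPE masses are probabilities, never rescaled
    assert pct["rope_mass"].dropna().to_numpy() == pytest.approx(
        plain["rope_mass"].dropna().to_numpy()
    )


def test_summary_degenerate_posterior():
    from cgtcal.inference import PosteriorDraws

    draws = PosteriorDraws(
        {"female": np.full((2, 500), 2.0)}, ["female"],
        ModelSpec("y", ("female",), IDENTITY), MCMCConfig(2, 10, 500, 1, 0),
    )
    with pytest.raises(DegenerateChainsError):
        summarize(draws)
    # the point summaries themselves are exact
    assert draws.pM("female") == 2.0
    assert draws.pSD("female") == 0.0
    assert draws.hpd("female") == (2.0, 2.0)
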