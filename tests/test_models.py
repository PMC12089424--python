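import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, t as student_t

from cogvar.decompose import bayes_r2
from cogvar.models import (
    ModelSpec,
    PriorSpec,
    SamplerConfig,
    ScoredDataset,
    design_matrix,
    fit_me,
    fit_standard,
    marginal_gls_fit,
    split_rhat,
    split_rhat_chains,
)
from conftest import make_regression_data

FAST = SamplerConfig(n_chains=3, n_iterations=1000, n_warmup=200, seed=0)


# --- independent oracles -------------------------------------------------

def grid_posterior_means(y, x, sems, n_grid=81):
    """Brute-force Riemann-sum evaluation of the marginalized posterior
    p(b0, b1, sigma | y) for y_i ~ N(b0 + b1 x_i, sigma^2 + sem_i^2) with
    flat slope prior, t(3, 0, 2.5) intercept prior, and t(3, 0.4, 2.5)
    residual-SD prior truncated to positives.  Written against scipy only.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_sd = np.std(y - X @ beta_ols, ddof=0) + 0.5
    scale = resid_sd / np.sqrt(len(y))
    b0 = np.linspace(beta_ols[0] - 25 * scale, beta_ols[0] + 25 * scale, n_grid)
    b1_sd = scale / max(np.std(x), 0.3)
    b1 = np.linspace(beta_ols[1] - 25 * b1_sd, beta_ols[1] + 25 * b1_sd, n_grid)
    sigma = np.linspace(1e-3, 12.0 * resid_sd, n_grid)

    logpost = np.empty((n_grid, n_grid, n_grid))
    for k, s in enumerate(sigma):
        total_sd = np.sqrt(s**2 + sems**2)
        mu = b0[:, None, None] + b1[None, :, None] * x[None, None, :]
        ll = norm.logpdf(y[None, None, :], loc=mu, scale=total_sd[None, None, :]).sum(axis=2)
        logpost[:, :, k] = ll + student_t.logpdf(s, 3, loc=0.4, scale=2.5)
    logpost += student_t.logpdf(b0, 3, loc=0.0, scale=2.5)[:, None, None]
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    # sanity: negligible mass at the open boundaries (the sigma lower edge
    # sits at the truncation point 0 and legitimately carries density)
    edge = w[[0, -1], :, :].sum() + w[:, [0, -1], :].sum() + w[:, :, -1].sum()
    assert edge < 1e-3, "grid too narrow for the posterior"
    return (
        float((w.sum(axis=(1, 2)) * b0).sum()),
        float((w.sum(axis=(0, 2)) * b1).sum()),
        float((w.sum(axis=(0, 1)) * sigma).sum()),
    )


def reference_split_rhat(chains):
    """Split-chain R-hat re-derived from the textbook formula."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.append(np.asarray(c[:h], dtype=float))
        halves.append(np.asarray(c[h:2 * h], dtype=float))
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    w = variances.mean()
    b = n * means.var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


# --- fit_standard --------------------------------------------------------

class TestFitStandard:
    def test_recovers_known_truth(self, simple_spec):
        data = make_regression_data(500, beta0=2.0, beta1=1.0, sigma=1.0, seed=1)
        draws = fit_standard(data, simple_spec, config=FAST)
        summ = draws.summary().set_index("parameter")
        for name, truth in [("intercept", 2.0), ("x", 1.0), ("sigma", 1.0)]:
            row = summ.loc[name]
            assert abs(row["mean"] - truth) < 3 * row["sd"], name

    def test_flat_prior_matches_ols(self, simple_spec):
        data = make_regression_data(2000, seed=2)
        draws = fit_standard(data, simple_spec, config=FAST)
        X, y, _, _ = design_matrix(data, simple_spec)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(draws.beta.mean(axis=0) - beta_ols)) < 0.02

    def test_duplicated_predictor_rejected(self):
        df = make_regression_data(50, seed=3).frame
        df["x2"] = df["x"]
        data = ScoredDataset(df)
        spec = ModelSpec(outcome="score", biomarkers=("x", "x2"), phase=None)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_standard(data, spec, config=FAST)

    def test_draw_count_and_positivity(self, simple_spec):
        data = make_regression_data(100, seed=4)
        cfg = SamplerConfig(n_chains=3, n_iterations=400, n_warmup=100, seed=0)
        draws = fit_standard(data, simple_spec, config=cfg)
        assert draws.n_draws == 3 * 300
        assert np.all(draws.sigma > 0)
        assert sorted(np.unique(draws.chain)) == [0, 1, 2]

    def test_missing_rows_dropped(self, simple_spec, caplog):
        df = make_regression_data(50, seed=5).frame
        df.loc[3, "x"] = np.nan
        data = ScoredDataset(df)
        X, y, _, rows = design_matrix(data, simple_spec)
        assert len(y) == 49 and 3 not in rows

    def test_seed_determinism(self, simple_spec):
        data = make_regression_data(100, seed=6)
        a = fit_standard(data, simple_spec, config=FAST)
        b = fit_standard(data, simple_spec, config=FAST)
        assert np.array_equal(a.beta, b.beta) and np.array_equal(a.sigma, b.sigma)


# --- fit_me --------------------------------------------------------------

class TestFitMe:
    def test_degenerate_sem_matches_standard(self, simple_spec, simple_me_spec):
        data = make_regression_data(400, sigma=0.8, sem=1e-6, seed=7)
        d_std = fit_standard(data, simple_spec, config=FAST)
        d_me = fit_me(data, simple_me_spec, config=FAST)
        diff = np.abs(np.append(d_std.beta.mean(axis=0), d_std.sigma.mean())
                      - np.append(d_me.beta.mean(axis=0), d_me.sigma.mean()))
        assert diff.max() < 0.02

    def test_grid_oracle_small_n(self, simple_me_spec):
        data = make_regression_data(5, beta0=0.5, beta1=0.8, sigma=0.6, sem=0.4, seed=8)
        # heavy posterior tails at n=5: long chains keep MC error << tolerance
        cfg = SamplerConfig(n_chains=3, n_iterations=20_000, n_warmup=1000, seed=1)
        draws = fit_me(data, simple_me_spec, config=cfg)
        df = data.frame
        want = grid_posterior_means(df["score"].to_numpy(), df["x"].to_numpy(),
                                    df["sem"].to_numpy(), n_grid=161)
        got = (draws.parameter("intercept").mean(), draws.parameter("x").mean(),
               draws.sigma.mean())
        assert np.max(np.abs(np.array(got) - np.array(want))) < 0.02

    def test_sigma_recovery_and_standard_inflation(self, simple_spec, simple_me_spec):
        rng = np.random.default_rng(9)
        sems = rng.uniform(0.3, 0.6, size=500)
        data = make_regression_data(500, sigma=0.5, sem=sems, seed=9)
        d_me = fit_me(data, simple_me_spec, config=FAST)
        mean, sd = d_me.sigma.mean(), d_me.sigma.std(ddof=1)
        assert abs(mean - 0.5) < 3 * sd
        d_std = fit_standard(data, simple_spec, config=FAST)
        assert d_std.sigma.mean() > 0.5

    def test_negative_sem_rejected(self, simple_me_spec):
        df = make_regression_data(20, sem=0.3, seed=10).frame
        df.loc[0, "sem"] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            fit_me(ScoredDataset(df), simple_me_spec, config=FAST)

    def test_missing_sem_column_rejected(self, simple_me_spec):
        df = make_regression_data(20, seed=11).frame.drop(columns="sem")
        with pytest.raises(ValueError, match="SEM column"):
            fit_me(ScoredDataset(df), simple_me_spec, config=FAST)

    def test_latent_draws_shape_and_zero_sem_fix(self, simple_me_spec):
        df = make_regression_data(30, sem=0.4, seed=12).frame
        df.loc[0, "sem"] = 0.0
        cfg = SamplerConfig(n_chains=2, n_iterations=200, n_warmup=100, seed=0,
                            save_latent=True)
        draws = fit_me(ScoredDataset(df), simple_me_spec, config=cfg)
        assert draws.latent.shape == (draws.n_draws, 30)
        assert np.all(draws.latent[:, 0] == df.loc[0, "score"])

    def test_posterior_contraction(self, simple_me_spec):
        sds = []
        for n in (100, 400, 1600):
            data = make_regression_data(n, sem=0.4, seed=13)
            draws = fit_me(data, simple_me_spec, config=FAST)
            sds.append(draws.parameter("x").std(ddof=1))
        assert sds[0] > sds[1] > sds[2]

    def test_prior_sensitivity_on_r2(self, simple_spec):
        data = make_regression_data(1084, seed=14)
        X, _, _, _ = design_matrix(data, simple_spec)
        r2 = []
        for scale in (2.5, 5.0):
            priors = PriorSpec(intercept_scale=scale)
            draws = fit_standard(data, simple_spec, priors=priors, config=FAST)
            r2.append(bayes_r2(draws, X).r2.mean())
        assert abs(r2[0] - r2[1]) < 0.005

    def test_convergence_gate_passes_on_healthy_fit(self, simple_me_spec):
        data = make_regression_data(200, sem=0.3, seed=15)
        draws = fit_me(data, simple_me_spec, config=FAST)
        assert draws.converged(1.05)
        assert draws.max_rhat() < 1.05


# --- marginal GLS oracle -------------------------------------------------

class TestMarginalGls:
    def test_zero_sem_reduces_to_ols(self, simple_spec):
        data = make_regression_data(80, seed=16)
        beta, sigma2 = marginal_gls_fit(data, simple_spec)
        X, y, _, _ = design_matrix(data, simple_spec)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        assert beta == pytest.approx(beta_ols, abs=1e-6)
        assert sigma2 == pytest.approx(rss / len(y), rel=1e-4)

    def test_agrees_with_fit_me(self, simple_me_spec):
        data = make_regression_data(300, sigma=0.7, sem=0.4, seed=17)
        beta_gls, sigma2_gls = marginal_gls_fit(data, simple_me_spec)
        draws = fit_me(data, simple_me_spec, config=FAST)
        assert np.max(np.abs(draws.beta.mean(axis=0) - beta_gls)) < 0.05
        assert abs(draws.sigma.mean() - np.sqrt(sigma2_gls)) < 0.05

    def test_sigma2_nonnegative_at_boundary(self, simple_me_spec):
        # observation noise alone over-explains the variance => ML sigma^2 ~ 0
        rng = np.random.default_rng(18)
        n = 100
        x = rng.standard_normal(n)
        sem = np.full(n, 1.0)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.2, size=n)  # much less spread than sem claims
        data = ScoredDataset(pd.DataFrame({"score": y, "x": x, "sem": sem}))
        _, sigma2 = marginal_gls_fit(data, simple_me_spec)
        assert sigma2 >= 0.0
        assert sigma2 < 0.05


# --- split R-hat ---------------------------------------------------------

class TestSplitRhat:
    def test_matches_reference_on_random_chains(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            chains = rng.normal(size=(4, 100)) * rng.uniform(0.5, 2) + rng.uniform(-1, 1)
            assert split_rhat_chains(chains) == pytest.approx(
                reference_split_rhat(chains), abs=1e-10)

    def test_converged_limit(self):
        rng = np.random.default_rng(20)
        chains = rng.normal(size=(4, 20_000))
        assert 0.99 < split_rhat_chains(chains) < 1.01

    def test_flags_bimodal_chains(self):
        rng = np.random.default_rng(21)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert split_rhat_chains(chains) > 1.05

    def test_zero_within_variance_warns_nan(self):
        chains = np.stack([np.full(10, 1.0), np.full(10, 2.0)])
        with pytest.warns(RuntimeWarning, match="zero within-chain"):
            assert np.isnan(split_rhat_chains(chains))

    def test_named_parameter_interface(self, simple_spec):
        data = make_regression_data(100, seed=22)
        draws = fit_standard(data, simple_spec, config=FAST)
        assert split_rhat(draws, "sigma") == pytest.approx(draws.rhat["sigma"])
        with pytest.raises(KeyError):
            draws.parameter("nope")

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            split_rhat_chains(np.ones((1, 100)))


# --- persistence ---------------------------------------------------------

def test_draws_long_table_roundtrip(simple_spec):
    data = make_regression_data(60, seed=23)
    cfg = SamplerConfig(n_chains=2, n_iterations=120, n_warmup=20, seed=0)
    draws = fit_standard(data, simple_spec, config=cfg)
    long = draws.to_frame()
    assert set(long.columns) == {"chain", "draw", "parameter", "value"}
    assert len(long) == draws.n_draws * 3  # intercept, x, sigma
    summ = draws.summary()
    assert list(summ.columns) == ["parameter", "mean", "sd", "q2.5", "q97.5", "rhat"]
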