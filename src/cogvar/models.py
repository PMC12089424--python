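"""Bayesian normal linear models with and without outcome measurement error.

Two fits share one sampler core:

* ``fit_standard``: observed score_i ~ Normal(x_i' beta, sigma^2).
* ``fit_me``: observed score_i ~ Normal(theta_i, sem_i^2) with latent
  theta_i ~ Normal(x_i' beta, sigma^2) and per-person sem_i known.  The
  latent layer is marginalized analytically -- score_i ~ Normal(x_i' beta,
  sigma^2 + sem_i^2) -- so (beta, sigma) are sampled from the collapsed
  posterior; latent draws are regenerated from their exact normal
  conditional when requested.

Priors follow the reference analysis: improper flat priors on slope
coefficients, Student-t(3, 0, 2.5) on the intercept, and Student-t(3, 0.4,
2.5) truncated to positives on the residual SD.  The intercept's t prior
is handled exactly through its scale-mixture-of-normals representation
(an auxiliary inverse-gamma variance), so the beta update stays a
closed-form multivariate normal; sigma uses an adaptive random-walk
Metropolis step on log sigma.

A deterministic maximum-likelihood oracle (``marginal_gls_fit``) and
split-chain R-hat diagnostics are included for testing and convergence
gating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredDataset",
    "ModelSpec",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "design_matrix",
    "fit_standard",
    "fit_me",
    "marginal_gls_fit",
    "split_rhat",
    "split_rhat_chains",
]


@dataclass
class ScoredDataset:
    """One row per participant: observed score, its SEM, and regressors."""

    frame: pd.DataFrame
    score_col: str = "score"
    sem_col: str = "sem"

    def __post_init__(self) -> None:
        if self.score_col not in self.frame.columns:
            raise ValueError(f"missing score column {self.score_col!r}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ModelSpec:
    """Which regression to run.

    ``biomarkers`` may be empty (intercept/covariate-only model).  The
    phase covariate is always included when ``phase`` is set; ``tracer``
    should be set whenever an amyloid-type biomarker is among the
    regressors.  ``account_for_me`` selects the measurement-error model and
    requires ``sem_col`` on the dataset.
    """

    outcome: str
    biomarkers: tuple[str, ...] = ()
    phase: str | None = "phase"
    tracer: str | None = None
    account_for_me: bool = False

    @property
    def regressors(self) -> tuple[str, ...]:
        cols: list[str] = []
        if self.phase:
            cols.append(self.phase)
        cols.extend(self.biomarkers)
        if self.tracer:
            cols.append(self.tracer)
        return tuple(cols)


@dataclass(frozen=True)
class PriorSpec:
    intercept_df: float = 3.0
    intercept_loc: float = 0.0
    intercept_scale: float = 2.5
    sigma_df: float = 3.0
    sigma_loc: float = 0.4
    sigma_scale: float = 2.5
    # slope coefficients: improper flat prior

    def __post_init__(self) -> None:
        if self.intercept_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.intercept_df <= 0 or self.sigma_df <= 0:
            raise ValueError("prior degrees of freedom must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 3
    n_iterations: int = 1000
    n_warmup: int = 200
    seed: int = 0
    rhat_threshold: float = 1.05
    save_latent: bool = False

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("warmup must be smaller than the iteration count")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain structure.

    ``beta`` has shape (n_draws, p) with columns ``param_names[:p]``;
    ``sigma`` is the residual SD per draw; ``chain`` indexes the chain each
    draw came from.  ``latent`` (optional) holds draws of the latent true
    scores for measurement-error fits, shape (n_draws, n_obs).
    """

    beta: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    param_names: tuple[str, ...]
    rhat: dict[str, float] = field(default_factory=dict)
    latent: np.ndarray | None = None
    row_index: np.ndarray | None = None  # analysis rows used, for pairing checks
    accept_rate: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma draws must be positive")
        if self.beta.shape[0] != self.sigma.shape[0]:
            raise ValueError("beta and sigma draw counts differ")

    @property
    def n_draws(self) -> int:
        return self.sigma.shape[0]

    def parameter(self, name: str) -> np.ndarray:
        if name == "sigma":
            return self.sigma
        try:
            j = self.param_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc
        return self.beta[:, j]

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def converged(self, threshold: float = 1.05) -> bool:
        return all(np.isfinite(v) and v < threshold for v in self.rhat.values())

    def to_frame(self) -> pd.DataFrame:
        """Long table (chain, draw, parameter, value)."""
        records = []
        n = self.n_draws
        draw_ids = np.arange(n)
        for j, name in enumerate(self.param_names):
            records.append(pd.DataFrame(
                {"chain": self.chain, "draw": draw_ids, "parameter": name,
                 "value": self.beta[:, j]}))
        records.append(pd.DataFrame(
            {"chain": self.chain, "draw": draw_ids, "parameter": "sigma",
             "value": self.sigma}))
        return pd.concat(records, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in (*self.param_names, "sigma"):
            x = self.parameter(name)
            rows.append({
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": float(np.percentile(x, 2.5)),
                "q97.5": float(np.percentile(x, 97.5)),
                "rhat": self.rhat.get(name, float("nan")),
            })
        return pd.DataFrame(rows)


def design_matrix(data: ScoredDataset, model: ModelSpec) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], np.ndarray]:
    """Build (X, y, names, kept_row_positions) after complete-case filtering.

    Raises on rank deficiency, naming the offending columns.
    """
    cols = [model.outcome, *model.regressors]
    if model.account_for_me:
        if data.sem_col not in data.frame.columns:
            raise ValueError(f"measurement-error model requires SEM column {data.sem_col!r}")
        cols.append(data.sem_col)
    missing = [c for c in cols if c not in data.frame.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    sub = data.frame[cols]
    keep = sub.notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, len(sub))
    sub = sub.loc[keep]
    if len(sub) == 0:
        raise ValueError("no complete-case rows remain")
    y = sub[model.outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))] +
                        [sub[c].to_numpy(dtype=float) for c in model.regressors])
    names = ("intercept", *model.regressors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, y, names, np.flatnonzero(keep)


def _collinear_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in np.flatnonzero(diag < tol)]


def _log_sigma_prior(sigma: float, priors: PriorSpec) -> float:
    z = (sigma - priors.sigma_loc) / priors.sigma_scale
    return -0.5 * (priors.sigma_df + 1.0) * np.log1p(z * z / priors.sigma_df)


def _marginal_loglik(y: np.ndarray, mean: np.ndarray, total_var: np.ndarray) -> float:
    resid = y - mean
    return float(-0.5 * np.sum(np.log(total_var) + resid * resid / total_var))


def _run_chain(
    X: np.ndarray,
    y: np.ndarray,
    sem2: np.ndarray,
    priors: PriorSpec,
    config: SamplerConfig,
    rng: np.random.Generator,
    beta0: np.ndarray,
    sigma0: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One chain of the collapsed sampler; returns retained (beta, sigma)."""
    n, p = X.shape
    nu_i = priors.intercept_df
    s_i2 = priors.intercept_scale**2
    homoscedastic = not np.any(sem2 > 0)
    if homoscedastic:
        xtx = X.T @ X
        xty = X.T @ y

    beta = beta0.copy()
    sigma = float(sigma0)
    psi = 1.0  # intercept scale-mixture auxiliary variance
    step = 0.5 / np.sqrt(n)
    n_keep = config.n_iterations - config.n_warmup
    betas = np.empty((n_keep, p))
    sigmas = np.empty(n_keep)
    accepted = 0
    proposed = 0
    window_acc = 0
    window_n = 0

    total_var = sigma**2 + sem2
    for it in range(config.n_iterations):
        # --- intercept auxiliary variance: t prior as normal/inv-gamma mixture
        b0c = beta[0] - priors.intercept_loc
        shape = 0.5 * (nu_i + 1.0)
        rate = 0.5 * (nu_i + b0c * b0c / s_i2)
        psi = rate / rng.gamma(shape)

        # --- beta | sigma, psi: conjugate multivariate normal
        if homoscedastic:
            prec = xtx / (sigma**2)
            rhs = xty / (sigma**2)
        else:
            w = 1.0 / total_var
            prec = (X * w[:, None]).T @ X
            rhs = X.T @ (w * y)
        prec = prec.copy()
        prec[0, 0] += 1.0 / (s_i2 * psi)
        rhs = rhs.copy()
        rhs[0] += priors.intercept_loc / (s_i2 * psi)
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(chol.T, z)

        # --- sigma: random-walk Metropolis on log sigma
        mu = X @ beta
        log_sigma = np.log(sigma)
        cur = (_marginal_loglik(y, mu, total_var)
               + _log_sigma_prior(sigma, priors) + log_sigma)
        prop_log_sigma = log_sigma + step * rng.standard_normal()
        prop_sigma = float(np.exp(prop_log_sigma))
        prop_total = prop_sigma**2 + sem2
        prop = (_marginal_loglik(y, mu, prop_total)
                + _log_sigma_prior(prop_sigma, priors) + prop_log_sigma)
        proposed += 1
        window_n += 1
        if np.log(rng.uniform()) < prop - cur:
            sigma = prop_sigma
            total_var = prop_total
            accepted += 1
            window_acc += 1

        # --- step-size adaptation during warmup, targeting ~35% acceptance
        if it < config.n_warmup and window_n >= 25:
            rate_hat = window_acc / window_n
            step *= float(np.exp(rate_hat - 0.35))
            window_acc = 0
            window_n = 0

        if it >= config.n_warmup:
            k = it - config.n_warmup
            betas[k] = beta
            sigmas[k] = sigma

    return betas, sigmas, accepted / max(proposed, 1)


def _fit(
    data: ScoredDataset,
    model: ModelSpec,
    priors: PriorSpec,
    config: SamplerConfig,
    use_sem: bool,
) -> PosteriorDraws:
    X, y, names, rows = design_matrix(data, model)
    n, p = X.shape
    if use_sem:
        sem = data.frame[data.sem_col].to_numpy(dtype=float)[rows]
        if np.any(~np.isfinite(sem)) or np.any(sem < 0):
            raise ValueError("SEM values must be finite and nonnegative")
        sem2 = sem**2
    else:
        sem2 = np.zeros(n)

    # overdispersed-but-sane starts around the OLS solution
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    sigma_ols = float(np.sqrt(max(resid @ resid / max(n - p, 1), 1e-6)))

    master = np.random.default_rng(config.seed)
    all_beta, all_sigma, all_chain = [], [], []
    acc_rates = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(master.integers(2**63))
        beta0 = beta_ols + 0.1 * sigma_ols * rng.standard_normal(p)
        sigma0 = sigma_ols * float(np.exp(0.2 * rng.standard_normal()))
        betas, sigmas, acc = _run_chain(X, y, sem2, priors, config, rng, beta0, sigma0)
        all_beta.append(betas)
        all_sigma.append(sigmas)
        all_chain.append(np.full(betas.shape[0], c))
        acc_rates.append(acc)

    beta = np.concatenate(all_beta)
    sigma = np.concatenate(all_sigma)
    chain = np.concatenate(all_chain)
    draws = PosteriorDraws(
        beta=beta, sigma=sigma, chain=chain, param_names=names,
        row_index=rows, accept_rate=float(np.mean(acc_rates)),
    )
    n_keep = config.n_iterations - config.n_warmup
    for name in (*names, "sigma"):
        mat = draws.parameter(name).reshape(config.n_chains, n_keep)
        draws.rhat[name] = split_rhat_chains(mat)

    if use_sem and config.save_latent:
        draws.latent = _draw_latent(X, y, sem2, beta, sigma, np.random.default_rng(config.seed + 1))
    return draws


def _draw_latent(
    X: np.ndarray,
    y: np.ndarray,
    sem2: np.ndarray,
    beta: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact conditional draws of the latent true scores given (beta, sigma).

    Rows with sem == 0 have latent fixed at the observed value (the
    degenerate limit of the measurement layer).
    """
    n_draws = sigma.shape[0]
    out = np.empty((n_draws, y.size))
    zero = sem2 == 0
    for d in range(n_draws):
        s2 = sigma[d] ** 2
        mu = X @ beta[d]
        prec = 1.0 / s2 + np.where(zero, np.inf, 1.0 / np.where(zero, 1.0, sem2))
        var = 1.0 / prec
        mean = var * (mu / s2 + np.where(zero, 0.0, y / np.where(zero, 1.0, sem2)))
        draw = mean + np.sqrt(var) * rng.standard_normal(y.size)
        out[d] = np.where(zero, y, draw)
    return out


def fit_standard(
    data: ScoredDataset,
    model: ModelSpec,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Fit the standard model: observed score regressed on the covariates,
    measurement error ignored."""
    return _fit(data, model, priors or PriorSpec(), config or SamplerConfig(), use_sem=False)


def fit_me(
    data: ScoredDataset,
    model: ModelSpec,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Fit the measurement-error model: latent true score regressed on the
    covariates, observed score ~ Normal(latent, sem^2) with known per-person
    sem."""
    return _fit(data, model, priors or PriorSpec(), config or SamplerConfig(), use_sem=True)


def marginal_gls_fit(data: ScoredDataset, model: ModelSpec) -> tuple[np.ndarray, float]:
    """Deterministic ML oracle for score_i ~ Normal(x_i' beta, sigma^2 + sem_i^2).

    Profiles the likelihood over sigma^2 (weighted least squares for beta at
    each candidate).  With all sem = 0 this reduces to OLS beta and the ML
    residual variance.  Returns (beta_hat, sigma2_hat).
    """
    spec = ModelSpec(outcome=model.outcome, biomarkers=model.biomarkers,
                     phase=model.phase, tracer=model.tracer, account_for_me=True)
    try:
        X, y, names, rows = design_matrix(data, spec)
        sem = data.frame[data.sem_col].to_numpy(dtype=float)[rows]
    except ValueError:
        # no sem column: treat as zero measurement error
        X, y, names, rows = design_matrix(data, model)
        sem = np.zeros(y.size)
    sem2 = sem**2
    n = y.size

    def neg_profile_ll(sigma2: float) -> float:
        total = sigma2 + sem2
        w = 1.0 / total
        xw = X * w[:, None]
        beta = np.linalg.solve(xw.T @ X, xw.T @ y)
        resid = y - X @ beta
        return 0.5 * float(np.sum(np.log(total) + resid * resid * w))

    upper = max(10.0 * float(np.var(y)), 1.0)
    res = minimize_scalar(neg_profile_ll, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(
            f"profile likelihood search failed on bracket (0, {upper}): {res.message}")
    sigma2_hat = float(res.x)
    total = sigma2_hat + sem2
    w = 1.0 / total
    xw = X * w[:, None]
    beta_hat = np.linalg.solve(xw.T @ X, xw.T @ y)
    return beta_hat, sigma2_hat


def split_rhat_chains(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Each chain is halved, then
    R-hat = sqrt(((n-1)/n * W + B/n) / W) over the 2*n_chains half-chains.
    Returns NaN (with a warning) when the within-chain variance is zero.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = split.shape
    within = split.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0:
        warnings.warn("zero within-chain variance; R-hat undefined", RuntimeWarning)
        return float("nan")
    b = n * split.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(draws: PosteriorDraws, parameter: str) -> float:
    """Split-chain R-hat for one named parameter of a fit."""
    values = draws.parameter(parameter)
    chain_ids = np.unique(draws.chain)
    if chain_ids.size < 2:
        raise ValueError("need at least 2 chains")
    per_chain = [values[draws.chain == c] for c in chain_ids]
    n = min(len(v) for v in per_chain)
    mat = np.stack([v[:n] for v in per_chain])
    return split_rhat_chains(mat)
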