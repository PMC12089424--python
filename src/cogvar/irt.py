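"""Graded-response item banks, EAP scoring, and measurement-precision curves.

The measurement model is the logistic graded response model (GRM): for an
item with discrimination ``a`` and strictly increasing thresholds
``b_1 < ... < b_{K-1}``,

    P(Y >= k | theta) = logistic(a * (theta - b_k)),   k = 1..K-1,

with category probabilities obtained by differencing adjacent cumulative
curves.  Binary items are the K=2 special case (a 2PL).

Scores are expected-a-posteriori (EAP) estimates: the posterior mean of the
latent trait given a person's responses under a normal prior, evaluated by
fixed quadrature.  The per-person standard error of measurement (SEM) is
the matching posterior SD.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "Item",
    "ItemBank",
    "QuadratureGrid",
    "ScoreWithSEM",
    "category_probabilities",
    "simulate_responses",
    "eap_score",
    "eap_score_matrix",
    "test_information",
    "sem_curve",
    "standardize_scores",
    "memory_like_bank",
    "visuospatial_like_bank",
    "read_item_bank",
    "write_item_bank",
]


@dataclass(frozen=True)
class Item:
    """One graded-response item: discrimination ``a`` and thresholds ``b``."""

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item discrimination must be positive, got {self.a}")
        b = np.asarray(self.b, dtype=float)
        if b.size < 1:
            raise ValueError("item needs at least one threshold (K >= 2)")
        if not np.all(np.isfinite(b)):
            raise ValueError("item thresholds must be finite")
        if b.size > 1 and not np.all(np.diff(b) > 0):
            raise ValueError(f"item thresholds must be strictly increasing, got {self.b}")
        object.__setattr__(self, "b", tuple(float(x) for x in b))

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class ItemBank:
    """A set of items measuring one cognitive domain."""

    items: tuple[Item, ...]
    domain_label: str = ""

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if len(items) < 1:
            raise ValueError("item bank must contain at least one item")
        if not all(isinstance(it, Item) for it in items):
            raise TypeError("all bank entries must be Item instances")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class QuadratureGrid:
    """Ordered latent-trait nodes with (normalized) prior-mass weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least 2 one-dimensional nodes")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("grid nodes must be strictly increasing")
        if weights.shape != nodes.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive and align with nodes")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def from_normal_prior(
        cls,
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
        n_nodes: int = 61,
        span: float = 5.0,
    ) -> "QuadratureGrid":
        """Equally spaced nodes on ``prior_mean +/- span*prior_sd`` with
        renormalized normal-density weights (common IRT software default)."""
        if prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        nodes = np.linspace(prior_mean - span * prior_sd, prior_mean + span * prior_sd, n_nodes)
        weights = norm.pdf(nodes, loc=prior_mean, scale=prior_sd)
        return cls(nodes=nodes, weights=weights)


@dataclass(frozen=True)
class ScoreWithSEM:
    """EAP score and its posterior SD (the standard error of measurement)."""

    theta_hat: float
    sem: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta_hat) or not np.isfinite(self.sem) or self.sem <= 0:
            raise ValueError("score and SEM must be finite with SEM > 0")


def _cumulative_probs(item: Item, theta: np.ndarray) -> np.ndarray:
    """P(Y >= k | theta) for k=1..K-1; shape (len(theta), K-1)."""
    b = np.asarray(item.b)
    return expit(item.a * (theta[:, None] - b[None, :]))


def _category_prob_matrix(item: Item, theta: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (len(theta), K)."""
    cum = _cumulative_probs(item, theta)
    ones = np.ones((theta.size, 1))
    zeros = np.zeros((theta.size, 1))
    upper = np.concatenate([ones, cum], axis=1)
    lower = np.concatenate([cum, zeros], axis=1)
    return upper - lower


def category_probabilities(item: Item, theta: float) -> np.ndarray:
    """Probability of each of the item's K ordered categories at ``theta``."""
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return _category_prob_matrix(item, np.array([theta]))[0]


def simulate_responses(thetas: np.ndarray, bank: ItemBank, seed: int) -> np.ndarray:
    """Draw a persons-by-items matrix of ordered category codes (0-based)."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("theta vector must be non-empty")
    if not np.all(np.isfinite(thetas)):
        raise ValueError("all thetas must be finite")
    rng = np.random.default_rng(seed)
    out = np.empty((thetas.size, len(bank)), dtype=np.int64)
    for j, item in enumerate(bank.items):
        # inverse-CDF draw on the cumulative curves: response = number of
        # thresholds exceeded by the uniform draw
        cum = _cumulative_probs(item, thetas)  # P(Y >= k)
        u = rng.uniform(size=thetas.size)
        out[:, j] = (u[:, None] < cum).sum(axis=1)
    return out


def _log_likelihood_on_grid(responses: np.ndarray, bank: ItemBank, nodes: np.ndarray) -> np.ndarray:
    responses = np.asarray(responses)
    if responses.shape != (len(bank),):
        raise ValueError(
            f"response vector length {responses.shape} does not match bank size {len(bank)}"
        )
    loglik = np.zeros(nodes.size)
    for j, item in enumerate(bank.items):
        k = int(responses[j])
        if k == -1:  # sentinel: item not administered
            continue
        if k < 0 or k >= item.n_categories:
            raise ValueError(
                f"response {k} outside categories 0..{item.n_categories - 1} for item {j}"
            )
        probs = _category_prob_matrix(item, nodes)[:, k]
        loglik += np.log(np.clip(probs, 1e-300, None))
    return loglik


def eap_score(
    responses: np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> ScoreWithSEM:
    """EAP score and SEM for one person's response vector.

    ``grid`` defaults to 61 equally spaced nodes over prior_mean +/- 5 SD
    with normal-prior weights.  A response of -1 marks an item that was not
    administered; with every item missing the posterior equals the prior.
    """
    if grid is None:
        grid = QuadratureGrid.from_normal_prior(prior_mean, prior_sd)
    lo, hi = prior_mean - 5 * prior_sd, prior_mean + 5 * prior_sd
    if grid.nodes[0] > lo + 1e-9 or grid.nodes[-1] < hi - 1e-9:
        raise ValueError("grid must span at least prior_mean +/- 5*prior_sd")
    loglik = _log_likelihood_on_grid(responses, bank, grid.nodes)
    return _posterior_moments(loglik, grid)


def _posterior_moments(loglik: np.ndarray, grid: QuadratureGrid) -> ScoreWithSEM:
    logpost = loglik + np.log(grid.weights)
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    mean = float(post @ grid.nodes)
    var = float(post @ (grid.nodes - mean) ** 2)
    return ScoreWithSEM(theta_hat=mean, sem=float(np.sqrt(var)))


def eap_score_matrix(
    responses: np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EAP scoring of a persons-by-items response matrix.

    Returns ``(theta_hats, sems)``.  Used by the pipeline to score whole
    cohorts; identical per-person results to :func:`eap_score`.
    """
    if grid is None:
        grid = QuadratureGrid.from_normal_prior(prior_mean, prior_sd)
    responses = np.asarray(responses)
    if responses.ndim != 2 or responses.shape[1] != len(bank):
        raise ValueError("responses must be a persons-by-items matrix matching the bank")
    n = responses.shape[0]
    loglik = np.zeros((n, grid.nodes.size))
    for j, item in enumerate(bank.items):
        probs = _category_prob_matrix(item, grid.nodes)  # (nodes, K)
        k = responses[:, j].astype(np.int64)
        if k.min() < -1 or k.max() >= item.n_categories:
            raise ValueError(f"response outside category range for item {j}")
        observed = k != -1  # -1 marks a non-administered item
        contrib = np.log(np.clip(probs[:, np.where(observed, k, 0)].T, 1e-300, None))
        loglik += np.where(observed[:, None], contrib, 0.0)
    logpost = loglik + np.log(grid.weights)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    means = post @ grid.nodes
    variances = post @ grid.nodes**2 - means**2
    return means, np.sqrt(np.clip(variances, 1e-300, None))


def test_information(bank: ItemBank, theta: float) -> float:
    """Fisher information of the whole bank at ``theta``.

    Per item, I_j(theta) = sum_k (dP_k/dtheta)^2 / P_k; for a binary item
    this reduces to a^2 p (1-p).
    """
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    t = np.array([theta])
    total = 0.0
    for item in bank.items:
        cum = _cumulative_probs(item, t)[0]  # P(Y >= k), k=1..K-1
        dcum = item.a * cum * (1.0 - cum)  # derivative of each cumulative curve
        probs = category_probabilities(item, theta)
        # dP_k = dcum_{k} - dcum_{k+1} with boundary curves constant
        upper = np.concatenate([[0.0], dcum])
        lower = np.concatenate([dcum, [0.0]])
        dprobs = upper - lower
        mask = probs > 1e-12
        total += float(np.sum(dprobs[mask] ** 2 / probs[mask]))
    return total


def sem_curve(
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-node test information and expected-response EAP SEM.

    At each node theta0 the SEM is the posterior SD of a hypothetical
    respondent whose (fractional) responses equal their expectations at
    theta0, i.e. the likelihood is exp(E_{theta0}[log L(theta)]).
    """
    if grid is None:
        grid = QuadratureGrid.from_normal_prior(prior_mean, prior_sd)
    nodes = grid.nodes
    # expected log-likelihood surface: rows index theta0, cols index theta
    expected_ll = np.zeros((nodes.size, nodes.size))
    for item in bank.items:
        probs = _category_prob_matrix(item, nodes)  # (theta, K)
        logp = np.log(np.clip(probs, 1e-300, None))
        expected_ll += probs @ logp.T  # (theta0, theta)
    sems = np.empty(nodes.size)
    for i in range(nodes.size):
        sems[i] = _posterior_moments(expected_ll[i], grid).sem
    info = np.array([test_information(bank, t) for t in nodes])
    return pd.DataFrame({"theta": nodes, "sem": sems, "information": info})


def standardize_scores(
    scores: np.ndarray,
    reference_mean: float | None = None,
    reference_sd: float | None = None,
    sems: np.ndarray | None = None,
):
    """Scale scores to the reference mean/SD; divide SEMs by the same SD.

    With ``reference_mean``/``reference_sd`` omitted, the sample's own
    moments (SD with denominator n-1) are used, giving mean 0 / SD 1.
    Returns the standardized scores, or ``(scores, sems)`` if ``sems`` is
    provided.
    """
    scores = np.asarray(scores, dtype=float)
    if reference_mean is None:
        reference_mean = float(scores.mean())
    if reference_sd is None:
        reference_sd = float(scores.std(ddof=1))
    if not np.isfinite(reference_sd) or reference_sd <= 0:
        raise ValueError(f"reference_sd must be positive, got {reference_sd}")
    z = (scores - reference_mean) / reference_sd
    if sems is None:
        return z
    sems = np.asarray(sems, dtype=float) / reference_sd
    return z, sems


def memory_like_bank() -> ItemBank:
    """29 binary items, a in [1.0, 2.5], b in [-2, 1]: a high-information
    battery analogous to a large memory composite."""
    n = 29
    a = np.linspace(1.0, 2.5, n)
    b = np.linspace(-2.0, 1.0, n)
    items = tuple(Item(a=float(ai), b=(float(bi),)) for ai, bi in zip(a, b))
    return ItemBank(items=items, domain_label="memory_like")


def visuospatial_like_bank() -> ItemBank:
    """6 binary items, a in [0.8, 1.5], b in [-2.5, -1]: a short, easy
    battery with a ceiling effect and low information."""
    n = 6
    a = np.linspace(0.8, 1.5, n)
    b = np.linspace(-2.5, -1.0, n)
    items = tuple(Item(a=float(ai), b=(float(bi),)) for ai, bi in zip(a, b))
    return ItemBank(items=items, domain_label="visuospatial_like")


def write_item_bank(bank: ItemBank, path) -> None:
    """Persist a bank as a delimited table: item_id, model, a, K, b1..b_{Kmax-1}."""
    kmax = max(it.n_categories for it in bank.items)
    rows = []
    for i, it in enumerate(bank.items):
        row = {"item_id": f"{bank.domain_label or 'item'}_{i:03d}", "model": "grm",
               "a": it.a, "K": it.n_categories}
        for k in range(1, kmax):
            row[f"b{k}"] = it.b[k - 1] if k - 1 < len(it.b) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_item_bank(path, domain_label: str = "") -> ItemBank:
    df = pd.read_csv(path, sep="\t")
    required = {"item_id", "model", "a", "K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"item bank table missing columns: {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        if str(row["model"]) != "grm":
            raise ValueError(f"unsupported item model {row['model']!r}")
        k = int(row["K"])
        b = tuple(float(row[f"b{i}"]) for i in range(1, k))
        items.append(Item(a=float(row["a"]), b=b))
    return ItemBank(items=tuple(items), domain_label=domain_label)
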