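"""Poisson random field (PRF) inference of selection on site classes.

Given derived-allele counts at segregating sites grouped into classes (e.g.
ultraconserved elements, their flanks, nonsynonymous sites), this module
estimates the per-class mean and variance of the distribution of scaled
selection coefficients gamma = 2Ns for new mutations, via a hierarchical
Bayesian Metropolis-Hastings sampler. The sampling probability of a derived
count i out of n chromosomes follows the Sawyer-Hartl PRF stationary density

    f(x; gamma) = (1 - exp(-2 gamma (1 - x))) / ((1 - exp(-2 gamma)) x (1 - x)),

conditioned on segregation (1 <= i <= n-1), which cancels the mutation rate
theta. Classes ascertained by zero interspecific divergence can be weighted
by an exponential zero-fixation factor exp(-D * v(gamma)) with Kimura's
relative fixation rate v(gamma) = 2 gamma / (1 - exp(-2 gamma)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln

__all__ = [
    "SfsObservation",
    "ClassSelectionParams",
    "PosteriorSummary",
    "ClassPosterior",
    "prf_sfs_distribution",
    "prf_sfs_probability",
    "class_marginal_likelihood",
    "ascertainment_weight",
    "relative_fixation_rate",
    "McmcConfig",
    "McmcResult",
    "run_mcmc",
    "gelman_psrf",
    "summarize_posterior",
    "read_sfs_table",
    "observations_to_frame",
]

GAMMA_GUARD = 350.0  # |2*gamma| beyond this overflows exp() in float64


@dataclass(frozen=True)
class SfsObservation:
    """A segregating site: class label, derived count i, sample size n."""

    site_class: str
    derived_count: int
    sample_size: int

    def __post_init__(self):
        if self.sample_size < 2:
            raise ValueError("sample size must be >= 2")
        if not 1 <= self.derived_count <= self.sample_size - 1:
            raise ValueError(
                f"derived count {self.derived_count} outside [1, {self.sample_size - 1}]"
            )


@dataclass(frozen=True)
class ClassSelectionParams:
    """Mean and variance of the 2Ns distribution for new mutations."""

    mu: float
    sigma2: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


# ---------------------------------------------------------------------------
# PRF sampling probabilities


def _gl_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(order)
    return 0.5 * (x + 1.0), 0.5 * w  # mapped to (0, 1)


_KERNEL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _binomial_kernel(n: int, order: int) -> np.ndarray:
    """Rows i=1..n-1 of C(n,i) x^i (1-x)^(n-i) at the GL nodes, times weights."""
    key = (n, order)
    if key not in _KERNEL_CACHE:
        x, w = _gl_nodes(order)
        i = np.arange(1, n)[:, None]
        logc = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        logb = logc + i * np.log(x)[None, :] + (n - i) * np.log1p(-x)[None, :]
        _KERNEL_CACHE[key] = np.exp(logb) * w[None, :]
    return _KERNEL_CACHE[key]


def _density_at_nodes(gamma: float, x: np.ndarray) -> np.ndarray:
    """PRF density f(x; gamma) at quadrature nodes, stable for large |gamma|."""
    if abs(gamma) > GAMMA_GUARD:
        raise OverflowError(f"gamma = {gamma} exceeds the numerical guard {GAMMA_GUARD}")
    if abs(gamma) < 1e-9:
        return 1.0 / x
    a = -2.0 * gamma * (1.0 - x)  # exponent in the numerator
    b = -2.0 * gamma  # exponent in the denominator
    if gamma < 0:
        # both expm1 arguments are large positive: use exp(a-b) * stable ratio
        ratio = np.exp(a - b) * (-np.expm1(-a)) / (-math.expm1(-b))
    else:
        ratio = np.expm1(a) / math.expm1(b)
    return ratio / (x * (1.0 - x))


def _density_matrix(gammas: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized PRF density: rows index gamma values, columns x nodes."""
    g = np.asarray(gammas, dtype=float)[:, None]
    x = x[None, :]
    with np.errstate(over="ignore", invalid="ignore"):
        a = -2.0 * g * (1.0 - x)
        b = -2.0 * g
        neg = np.exp(a - b) * (-np.expm1(-a)) / (-np.expm1(-b))
        pos = np.expm1(a) / np.expm1(b)
        ratio = np.where(g < 0, neg, pos)
        ratio = np.where(np.abs(g) < 1e-9, 1.0 - x, ratio)  # gamma -> 0 limit
    return ratio / (x * (1.0 - x))


def prf_sfs_distribution(n: int, gamma: float, order: int = 50) -> np.ndarray:
    """P(i | n, gamma, segregating) for i = 1..n-1 (sums to 1 exactly).

    Computed by Gauss-Legendre quadrature of the binomial sampling kernel
    against the PRF density, normalized over the segregating counts.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    B = _binomial_kernel(n, order)
    f = _density_at_nodes(gamma, _gl_nodes(order)[0])
    I = B @ f
    return I / I.sum()


def prf_sfs_probability(i: int, n: int, gamma: float, order: int = 50) -> float:
    """Probability of derived count i among n sampled chromosomes."""
    if not 1 <= i <= n - 1:
        raise ValueError(f"derived count {i} outside [1, {n - 1}]")
    return float(prf_sfs_distribution(n, gamma, order=order)[i - 1])


def relative_fixation_rate(gamma) -> np.ndarray:
    """Kimura's fixation rate of a selected mutation relative to neutral.

    v(gamma) = 2 gamma / (1 - exp(-2 gamma)), with v(0) = 1. Monotone
    increasing in gamma; vanishes for strongly deleterious mutations.
    """
    g = np.asarray(gamma, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-2.0 * g)
        v = np.where(np.abs(g) < 1e-9, 1.0, 2.0 * g / np.where(denom == 0, 1.0, denom))
    return v


def ascertainment_weight(gamma, div_intensity: float) -> np.ndarray:
    """Probability of zero fixations during the ascertainment divergence.

    ``div_intensity`` is the expected number of neutral substitutions over
    the divergence used to ascertain elements; the weight
    exp(-div_intensity * v(gamma)) down-weights selection coefficients that
    would likely have produced a substitution, and increases as gamma
    decreases below zero.
    """
    if div_intensity < 0:
        raise ValueError("div_intensity must be >= 0")
    return np.exp(-div_intensity * relative_fixation_rate(gamma))


# ---------------------------------------------------------------------------
# Class marginal likelihood (integrating gamma over its class distribution)


def _aggregate(observations: Iterable[SfsObservation]) -> dict[int, np.ndarray]:
    """Group observations by sample size; value[n][i-1] = count of sites."""
    grouped: dict[int, np.ndarray] = {}
    for obs in observations:
        arr = grouped.setdefault(obs.sample_size, np.zeros(obs.sample_size - 1))
        arr[obs.derived_count - 1] += 1
    return grouped


class _ClassLikelihood:
    """Reusable likelihood evaluator for one site class (used by the MCMC)."""

    def __init__(
        self,
        observations: Sequence[SfsObservation],
        gh_order: int = 32,
        gl_order: int = 50,
        ascertained: bool = False,
        div_intensity: float = 0.0,
    ):
        if not observations:
            raise ValueError("observations must be non-empty")
        self.counts = _aggregate(observations)
        self.n_obs = len(observations)
        h, w = hermgauss(gh_order)
        self.gh_nodes = h
        self.gh_weights = w / math.sqrt(math.pi)
        self.gl_order = gl_order
        self.x_nodes = _gl_nodes(gl_order)[0]
        self.ascertained = ascertained
        self.div_intensity = div_intensity

    def log_likelihood(self, mu: float, sigma2: float) -> float:
        if sigma2 <= 0 or not np.isfinite(mu):
            return -np.inf
        gammas = mu + math.sqrt(2.0 * sigma2) * self.gh_nodes
        gammas = np.clip(gammas, -GAMMA_GUARD + 1, GAMMA_GUARD - 1)
        F = _density_matrix(gammas, self.x_nodes)  # (M, K)
        qw = self.gh_weights
        if self.ascertained and self.div_intensity > 0:
            qw = qw * ascertainment_weight(gammas, self.div_intensity)
            total = qw.sum()
            if total <= 0 or not np.isfinite(total):
                return -np.inf
            qw = qw / total
        ll = 0.0
        for n, counts in self.counts.items():
            B = _binomial_kernel(n, self.gl_order)  # (n-1, K)
            I = B @ F.T  # (n-1, M)
            P = I / I.sum(axis=0, keepdims=True)
            probs = P @ qw  # (n-1,)
            nz = counts > 0
            if (probs[nz] <= 0).any():
                return -np.inf
            ll += float(counts[nz] @ np.log(probs[nz]))
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite class likelihood at mu={mu}, sigma2={sigma2}"
            )
        return ll


def class_marginal_likelihood(
    observations: Sequence[SfsObservation],
    mu: float,
    sigma2: float,
    gh_order: int = 32,
    gl_order: int = 50,
    ascertained: bool = False,
    div_intensity: float = 0.0,
) -> float:
    """Log-likelihood of a class's SFS under gamma ~ Normal(mu, sigma2).

    The per-site probability integrates the PRF sampling probability over
    the class's Normal distribution of selection coefficients by
    Gauss-Hermite quadrature (order >= 8); per-site sample sizes may vary.
    For ascertained classes the Normal prior over gamma is reweighted by
    :func:`ascertainment_weight` and renormalized.
    """
    if gh_order < 8:
        raise ValueError("quadrature order must be >= 8")
    ev = _ClassLikelihood(
        observations, gh_order=gh_order, gl_order=gl_order,
        ascertained=ascertained, div_intensity=div_intensity,
    )
    return ev.log_likelihood(mu, sigma2)


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class McmcConfig:
    """Settings for the hierarchical sampler.

    Defaults mirror the reference analysis protocol: nine chains from overdispersed
    starting points, 1e5 iterations sampled every ten, first half burn-in.
    """

    n_chains: int = 9
    n_iters: int = 100_000
    thin: int = 10
    seed: int = 0
    ascertained: frozenset = frozenset()
    div_intensity: float = 0.0
    gh_order: int = 32
    gl_order: int = 50
    prior_mu_sd: float = 100.0
    prior_log_sigma_sd: float = 2.0
    start_mu_sd: float = 8.0
    start_log_sigma_sd: float = 0.7
    adapt_interval: int = 50
    target_acceptance: float = 0.3


@dataclass
class McmcResult:
    """Retained (post-burn-in, thinned) samples and bookkeeping.

    ``samples`` has shape (n_chains, n_kept, 2 * n_classes): per class the
    columns are (mu, log sigma). ``log_posts`` holds the unnormalized log
    posterior of each retained sample.
    """

    class_labels: list[str]
    samples: np.ndarray
    log_posts: np.ndarray
    acceptance: np.ndarray  # (n_chains, n_classes), post-burn-in rates
    n_obs: dict[str, int]
    config: McmcConfig
    flagged_chains: list[int] = field(default_factory=list)

    def class_samples(self, label: str) -> np.ndarray:
        """Pooled (mu, sigma2) samples for one class, shape (N, 2)."""
        k = self.class_labels.index(label)
        flat = self.samples.reshape(-1, self.samples.shape[-1])
        mu = flat[:, 2 * k]
        sigma2 = np.exp(2.0 * flat[:, 2 * k + 1])
        return np.column_stack([mu, sigma2])


def run_mcmc(
    data: Mapping[str, Sequence[SfsObservation]],
    config: McmcConfig | None = None,
) -> McmcResult:
    """Random-walk Metropolis-Hastings over per-class (mu, log sigma).

    Classes are a priori independent: each gets its own block proposal.
    Priors are weakly informative (mu ~ Normal(0, prior_mu_sd^2),
    log sigma ~ Normal(0, prior_log_sigma_sd^2)). Proposal scales adapt
    during burn-in toward the target acceptance rate and are frozen for the
    retained half, preserving detailed balance there. Runs are reproducible
    given the seed; chains with post-burn-in acceptance below 1% are
    flagged.
    """
    config = config or McmcConfig()
    labels = list(data)
    if not labels:
        raise ValueError("at least one site class is required")
    evaluators = [
        _ClassLikelihood(
            data[lab],
            gh_order=config.gh_order,
            gl_order=config.gl_order,
            ascertained=lab in config.ascertained,
            div_intensity=config.div_intensity,
        )
        for lab in labels
    ]
    n_classes = len(labels)
    n_iters, thin = config.n_iters, config.thin
    burn_in = n_iters // 2
    kept_idx0 = burn_in  # first retained iteration
    n_kept = (n_iters - burn_in) // thin
    samples = np.empty((config.n_chains, n_kept, 2 * n_classes))
    log_posts = np.empty((config.n_chains, n_kept))
    acceptance = np.zeros((config.n_chains, n_classes))
    flagged = []

    def log_prior(mu, log_sigma):
        return (
            -0.5 * (mu / config.prior_mu_sd) ** 2
            - 0.5 * (log_sigma / config.prior_log_sigma_sd) ** 2
        )

    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        state = np.empty((n_classes, 2))
        state[:, 0] = rng.normal(0.0, config.start_mu_sd, size=n_classes)
        state[:, 1] = rng.normal(0.0, config.start_log_sigma_sd, size=n_classes)
        lls = np.empty(n_classes)
        for k in range(n_classes):
            lls[k] = evaluators[k].log_likelihood(
                state[k, 0], math.exp(2 * state[k, 1])
            ) + log_prior(state[k, 0], state[k, 1])
            if not np.isfinite(lls[k]):
                raise ValueError(
                    f"non-finite posterior at chain {chain} start for class "
                    f"{labels[k]} (mu={state[k, 0]:.3f})"
                )
        scales = np.full(n_classes, 1.0)
        sigma_scales = np.full(n_classes, 1.0)
        # proposal shape: Cholesky factor of the per-class proposal
        # covariance, adapted from burn-in history and frozen afterwards
        chols = [np.eye(2) for _ in range(n_classes)]
        history = [[] for _ in range(n_classes)]
        accept_win = np.zeros(n_classes)
        accept_sigma_win = np.zeros(n_classes)
        accept_post = np.zeros(n_classes)
        kept = 0
        for it in range(n_iters):
            for k in range(n_classes):
                # joint covariance-shaped move
                prop = state[k] + scales[k] * (chols[k] @ rng.normal(size=2))
                ll_prop = evaluators[k].log_likelihood(
                    prop[0], math.exp(2 * prop[1])
                ) + log_prior(prop[0], prop[1])
                if np.isfinite(ll_prop) and math.log(rng.random()) < ll_prop - lls[k]:
                    state[k] = prop
                    lls[k] = ll_prop
                    accept_win[k] += 1
                    if it >= burn_in:
                        accept_post[k] += 1
                # log-sigma-only move: the spread of the 2Ns distribution can
                # be weakly identified, leaving a flat direction a joint
                # random walk traverses slowly
                prop = state[k].copy()
                prop[1] += sigma_scales[k] * rng.normal()
                ll_prop = evaluators[k].log_likelihood(
                    prop[0], math.exp(2 * prop[1])
                ) + log_prior(prop[0], prop[1])
                if np.isfinite(ll_prop) and math.log(rng.random()) < ll_prop - lls[k]:
                    state[k] = prop
                    lls[k] = ll_prop
                    accept_sigma_win[k] += 1
                if it < burn_in and it % 5 == 0:
                    history[k].append(state[k].copy())
            if it < burn_in and (it + 1) % config.adapt_interval == 0:
                rates = accept_win / config.adapt_interval
                scales *= np.exp(rates - config.target_acceptance)
                accept_win[:] = 0
                sigma_rates = accept_sigma_win / config.adapt_interval
                sigma_scales *= np.exp(sigma_rates - config.target_acceptance)
                accept_sigma_win[:] = 0
                for k in range(n_classes):
                    if len(history[k]) >= 100:
                        cov = np.cov(np.asarray(history[k][-2000:]).T)
                        cov = cov + 1e-6 * np.eye(2)
                        try:
                            chols[k] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass
            if it >= kept_idx0 and (it - kept_idx0) % thin == 0 and kept < n_kept:
                samples[chain, kept] = state.ravel()
                log_posts[chain, kept] = lls.sum()
                kept += 1
        acceptance[chain] = accept_post / (n_iters - burn_in)
        if (acceptance[chain] < 0.01).any():
            flagged.append(chain)
    return McmcResult(
        class_labels=labels,
        samples=samples,
        log_posts=log_posts,
        acceptance=acceptance,
        n_obs={lab: len(data[lab]) for lab in labels},
        config=config,
        flagged_chains=flagged,
    )


def gelman_psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    ``chains`` has shape (m, n, p) with m >= 2 chains of n retained samples
    of a p-vector. Returns R_hat = (n-1)/n + (m+1)/m * lambda_1, where
    lambda_1 is the largest eigenvalue of W^{-1} B / n; values near 1
    indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, p = chains.shape
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 10:
        raise ValueError("chains must retain at least 10 samples")
    chain_means = chains.mean(axis=1)  # (m, p)
    W = np.zeros((p, p))
    for j in range(m):
        dev = chains[j] - chain_means[j]
        W += dev.T @ dev / (n - 1)
    W /= m
    diag = np.diag(W)
    if (diag <= 0).any():
        bad = int(np.argmin(diag))
        raise ValueError(f"zero within-chain variance for parameter index {bad}")
    grand = chain_means.mean(axis=0)
    dev = chain_means - grand
    B_over_n = dev.T @ dev / (m - 1)  # = B / n
    lam = np.linalg.eigvals(np.linalg.solve(W, B_over_n))
    lam1 = float(np.max(lam.real))
    return (n - 1) / n + (m + 1) / m * lam1


@dataclass
class ClassPosterior:
    """Posterior summaries of one class's mean selection coefficient."""

    label: str
    n_obs: int
    posterior_mean: float
    map_estimate: float
    ci_low: float
    ci_high: float
    sigma2_posterior_mean: float
    sigma2_map: float


@dataclass
class PosteriorSummary:
    classes: list[ClassPosterior]
    psrf: float
    n_chains: int
    n_kept: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site_class": c.label,
                "n_snps": c.n_obs,
                "posterior_mean": c.posterior_mean,
                "map": c.map_estimate,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "sigma2_posterior_mean": c.sigma2_posterior_mean,
            }
            for c in self.classes
        ]
        return pd.DataFrame(rows)


def summarize_posterior(result: McmcResult) -> PosteriorSummary:
    """Posterior mean, MAP sample, and 95% equal-tailed CI per class.

    The MAP is the retained sample with the highest unnormalized log
    posterior; the CI uses the 2.5 and 97.5 percentiles of the pooled
    retained samples.
    """
    m, n_kept, _ = result.samples.shape
    pooled = result.samples.reshape(m * n_kept, -1)
    if pooled.shape[0] < 100:
        raise ValueError("need at least 100 pooled retained samples")
    map_idx = int(np.argmax(result.log_posts.ravel()))
    map_sample = pooled[map_idx]
    psrf = gelman_psrf(result.samples)
    classes = []
    for k, lab in enumerate(result.class_labels):
        mu = pooled[:, 2 * k]
        sigma2 = np.exp(2.0 * pooled[:, 2 * k + 1])
        lo, hi = np.percentile(mu, [2.5, 97.5])
        classes.append(
            ClassPosterior(
                label=lab,
                n_obs=result.n_obs[lab],
                posterior_mean=float(mu.mean()),
                map_estimate=float(map_sample[2 * k]),
                ci_low=float(lo),
                ci_high=float(hi),
                sigma2_posterior_mean=float(sigma2.mean()),
                sigma2_map=float(math.exp(2 * map_sample[2 * k + 1])),
            )
        )
    return PosteriorSummary(classes=classes, psrf=psrf, n_chains=m, n_kept=n_kept)


# ---------------------------------------------------------------------------
# I/O


def read_sfs_table(path) -> dict[str, list[SfsObservation]]:
    """Read a tab-delimited SFS table.

    Accepts either one row per SNP (``site_class  derived_count
    sample_size``) or aggregated rows with an additional ``count`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"site_class", "derived_count", "sample_size"}
    if not required <= set(df.columns):
        raise ValueError(f"SFS table must have columns {sorted(required)}")
    out: dict[str, list[SfsObservation]] = {}
    counts = df["count"] if "count" in df.columns else np.ones(len(df), dtype=int)
    for (_, row), c in zip(df.iterrows(), counts):
        obs = SfsObservation(
            site_class=str(row["site_class"]),
            derived_count=int(row["derived_count"]),
            sample_size=int(row["sample_size"]),
        )
        out.setdefault(obs.site_class, []).extend([obs] * int(c))
    return out


def observations_to_frame(data: Mapping[str, Sequence[SfsObservation]]) -> pd.DataFrame:
    rows = [
        {
            "site_class": o.site_class,
            "derived_count": o.derived_count,
            "sample_size": o.sample_size,
        }
        for obs in data.values()
        for o in obs
    ]
    return pd.DataFrame(rows)
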