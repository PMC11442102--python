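"""Bayesian calibration via adaptive Metropolis MCMC.

The likelihood is the Gaussian counterpart of the OLS cost with a single
shared noise variance σ² across the three stacked signals; priors are
uniform boxes over the a priori parameter ranges.  Proposals follow
Haario-style adaptive Metropolis: after a warm-up period the random-walk
covariance tracks the sample covariance of the chain's own history,
scaled by 2.4²/p, with a small diagonal regularizer.  σ² is refreshed
every iteration from its conjugate inverse-gamma conditional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .data import PVDataset
from .frequentist import bounds_for, cost_ols
from .model import ContractError, ModelConstants, ModelParameters, DEFAULT_FREE

__all__ = [
    "PriorSpec",
    "PosteriorChain",
    "log_likelihood",
    "log_prior",
    "adaptive_metropolis",
    "adaptive_metropolis_sample",
    "posterior_summary",
    "chain_diagnostics",
    "autocorrelation",
    "effective_sample_size",
]


@dataclass
class PriorSpec:
    """Independent uniform priors: parameter name → (lower, upper)."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ContractError(f"prior for {name!r} needs lower < upper")

    @classmethod
    def from_defaults(cls, free_names=DEFAULT_FREE) -> "PriorSpec":
        lo, hi = bounds_for(free_names)
        return cls(dict(zip(free_names, zip(lo, hi))))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return lo, hi


def log_likelihood(
    theta,
    sigma2: float,
    dataset: PVDataset,
    free_names=DEFAULT_FREE,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
) -> float:
    """Gaussian log-likelihood −(n/2)·ln(2πσ²) − J(θ)/(2σ²)."""
    if sigma2 <= 0:
        raise ContractError("sigma2 must be positive")
    n = 3 * dataset.n_samples
    j = cost_ols(theta, dataset, free_names, base_params, constants)
    if not np.isfinite(j) or j >= 1e11:  # sentinel → impossible
        return -np.inf
    return float(-(n / 2.0) * np.log(2.0 * np.pi * sigma2) - j / (2.0 * sigma2))


def log_prior(theta, priors: PriorSpec) -> float:
    """Uniform box prior: −Σ ln(width) inside (bounds inclusive), −inf outside."""
    lo, hi = priors.arrays()
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < lo) or np.any(theta > hi):
        return -np.inf
    return float(-np.sum(np.log(hi - lo)))


@dataclass
class PosteriorChain:
    """Adaptive-Metropolis sample paths with acceptance bookkeeping."""

    names: tuple[str, ...]
    samples: np.ndarray  # (n_iter, p)
    sigma2: np.ndarray  # (n_iter,)
    log_post: np.ndarray  # (n_iter,) log prior + log likelihood at σ²=1 scale
    accepted: np.ndarray  # (n_iter,) bool
    acceptance_rate: float
    seed: int
    burn_in: int
    adapt_start: int
    adapt_interval: int
    epsilon: float

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]

    def posterior(self, burn_in: int | None = None) -> np.ndarray:
        b = self.burn_in if burn_in is None else burn_in
        return self.samples[b:]

    def map_sample(self, burn_in: int | None = None) -> np.ndarray:
        """Retained sample with the highest posterior density."""
        b = self.burn_in if burn_in is None else burn_in
        return self.samples[b:][int(np.argmax(self.log_post[b:]))]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.samples, columns=list(self.names))
        frame["sigma2"] = self.sigma2
        frame["accepted"] = self.accepted.astype(int)
        return frame


def adaptive_metropolis(
    log_target,
    x0,
    n_iter: int,
    rng: np.random.Generator,
    init_proposal_sd,
    adapt_start: int = 1000,
    adapt_interval: int = 1,
    epsilon: float = 1e-10,
    callback=None,
):
    """Core Haario-style adaptive Metropolis random walk.

    ``log_target(x)`` may return −inf; after ``adapt_start`` iterations
    the proposal covariance is s_d·cov(history) + s_d·ε·I with
    s_d = 2.4²/p, refreshed every ``adapt_interval`` iterations.
    Returns (samples, log-target values, accepted flags).
    """
    x = np.asarray(x0, dtype=float).copy()
    p = x.size
    s_d = 2.4**2 / p
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ContractError("initial point has zero target density")
    samples = np.empty((n_iter, p))
    lps = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)
    chol = np.diag(np.asarray(init_proposal_sd, dtype=float))
    mean = x.copy()
    cov = np.zeros((p, p))
    for i in range(n_iter):
        prop = x + chol @ rng.standard_normal(p)
        lp_prop = float(log_target(prop))
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted[i] = True
        samples[i] = x
        lps[i] = lp
        if callback is not None:
            lp = callback(i, x, lp, bool(accepted[i]))
            lps[i] = lp
        # running mean/covariance of the history (Welford-style)
        w = 1.0 / (i + 2.0)
        delta = x - mean
        mean += w * delta
        cov += w * (np.outer(delta, x - mean) - cov)
        if i + 1 >= adapt_start and (i + 1 - adapt_start) % adapt_interval == 0:
            try:
                chol = np.linalg.cholesky(s_d * cov + s_d * epsilon * np.eye(p))
            except np.linalg.LinAlgError:
                pass
    return samples, lps, accepted


def adaptive_metropolis_sample(
    dataset: PVDataset,
    priors: PriorSpec | None = None,
    n_iter: int = 100_000,
    seed: int = 0,
    adapt_start: int = 1000,
    adapt_interval: int = 1,
    epsilon: float = 1e-10,
    burn_in_frac: float = 0.2,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
    initial: np.ndarray | None = None,
    sigma2_prior_n0: float = 1.0,
) -> PosteriorChain:
    """Sample the parameter posterior of the circuit model.

    Parameters move by adaptive Metropolis; the shared noise variance σ²
    is refreshed each iteration from its conjugate inverse-gamma
    conditional IG(a₀ + n/2, b₀ + J(θ)/2), with a weak prior (n₀ = 1)
    anchored at the mean squared residual of the starting point.
    Bit-reproducible under ``seed``.
    """
    priors = priors or PriorSpec.from_defaults()
    names = priors.names
    lo, hi = priors.arrays()
    base = base_params or ModelParameters()
    rng = np.random.default_rng(seed)
    n = 3 * dataset.n_samples

    if initial is None:
        from .model import PARAM_NAMES

        apriori = base.to_array()
        initial = np.clip(
            np.array([apriori[PARAM_NAMES.index(nm)] for nm in names]), lo, hi
        )
    initial = np.asarray(initial, dtype=float)

    j0 = cost_ols(initial, dataset, names, base, constants)
    s0_sq = max(j0 / n, 1e-12)
    a0 = 0.5 * sigma2_prior_n0
    b0 = 0.5 * sigma2_prior_n0 * s0_sq
    state = {"sigma2": s0_sq, "j_current": j0, "j_prop": np.nan}
    sigma2_path = np.empty(n_iter)
    lp_box = log_prior(initial, priors)

    def log_target(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        j = cost_ols(theta, dataset, names, base, constants)
        state["j_prop"] = j
        if not np.isfinite(j) or j >= 1e11:
            return -np.inf
        s2 = state["sigma2"]
        return -(n / 2.0) * np.log(2.0 * np.pi * s2) - j / (2.0 * s2) + lp_box

    def callback(i, x, lp, was_accepted):
        # Metropolis-within-Gibbs: conjugate σ² refresh from the current
        # residual sum of squares, then the current point's log target is
        # re-expressed under the new σ².
        if was_accepted:
            state["j_current"] = state["j_prop"]
        j = state["j_current"]
        state["sigma2"] = (b0 + j / 2.0) / rng.gamma(a0 + n / 2.0)
        sigma2_path[i] = state["sigma2"]
        s2 = state["sigma2"]
        return -(n / 2.0) * np.log(2.0 * np.pi * s2) - j / (2.0 * s2) + lp_box

    init_sd = 0.01 * (hi - lo)
    samples, lps, accepted = adaptive_metropolis(
        log_target,
        initial,
        n_iter,
        rng,
        init_sd,
        adapt_start=adapt_start,
        adapt_interval=adapt_interval,
        epsilon=epsilon,
        callback=callback,
    )
    rate = float(np.mean(accepted))
    if rate == 0.0 and n_iter > adapt_start:
        warnings.warn(
            f"no proposal accepted after adaptation (initial proposal sd {init_sd})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorChain(
        names=names,
        samples=samples,
        sigma2=sigma2_path,
        log_post=lps,
        accepted=accepted,
        acceptance_rate=rate,
        seed=seed,
        burn_in=int(burn_in_frac * n_iter),
        adapt_start=adapt_start,
        adapt_interval=adapt_interval,
        epsilon=epsilon,
    )


def _kde_mode(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)  # Scott/Silverman-class bandwidth
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def posterior_summary(
    chain: PosteriorChain, burn_in: int | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Marginal mean/median/mode (KDE peak), sd, and central credible
    intervals for every parameter and σ²."""
    b = chain.burn_in if burn_in is None else burn_in
    if b >= chain.n_iter:
        raise ContractError("burn-in longer than the chain")
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    rows = []
    cols = list(chain.names) + ["sigma2"]
    data = np.column_stack([chain.samples[b:], chain.sigma2[b:]])
    for name, x in zip(cols, data.T):
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "median": float(np.median(x)),
                "mode": _kde_mode(x),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "ci_lower": float(np.percentile(x, lo_q)),
                "ci_upper": float(np.percentile(x, hi_q)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Sample autocorrelation function up to ``max_lag``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    max_lag = max_lag or min(n - 1, 1000)
    xc = x - x.mean()
    var = float(xc @ xc)
    if var == 0:
        return np.zeros(max_lag + 1)
    acf = np.array([(xc[: n - k] @ xc[k:]) / var for k in range(max_lag + 1)])
    return acf


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation sum, truncated at the first
    non-positive autocorrelation (initial-positive-sequence rule)."""
    acf = autocorrelation(x)
    s = 0.0
    for k in range(1, acf.size):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(x.size / (1.0 + 2.0 * s))


def chain_diagnostics(chain: PosteriorChain, burn_in: int | None = None) -> pd.DataFrame:
    """Acceptance rate, lag-1 autocorrelation and ESS per parameter."""
    b = chain.burn_in if burn_in is None else burn_in
    rows = []
    for i, name in enumerate(chain.names):
        x = chain.samples[b:, i]
        acf = autocorrelation(x, max_lag=1)
        rows.append(
            {
                "parameter": name,
                "acceptance_rate": chain.acceptance_rate,
                "lag1_autocorr": float(acf[1]) if acf.size > 1 else 0.0,
                "ess": effective_sample_size(x),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
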