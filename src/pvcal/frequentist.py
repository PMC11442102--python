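"""Ordinary-least-squares calibration of the circuit model.

The cost is the unweighted, unscaled sum of squared differences between
the three measured signals (LV volume, LV pressure, aortic pressure) and
their simulated counterparts, stacked into one residual vector.  A
multistart strategy — bounded local minimization from many random initial
points — doubles as a practical-identifiability probe: tight agreement
among the best fits (small coefficient of variation) indicates a unique
global minimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import PVDataset
from .model import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    ContractError,
    ModelConstants,
    ModelParameters,
    stacked_output,
)

__all__ = [
    "residual_vector",
    "cost_ols",
    "multistart_fit",
    "top_k_cov",
    "information_criteria",
    "compare_subsets",
    "MultistartResult",
    "SubsetComparison",
]

log = logging.getLogger(__name__)

#: Cost assigned when a forward simulation fails, so optimizers can continue.
SENTINEL_COST = 1.0e12

_BOUNDS_WITH_RAV = dict(DEFAULT_BOUNDS, r_av=(1.0e-4, 1.0e-2))


def _assemble(theta_free, free_names, base: ModelParameters) -> ModelParameters:
    theta_free = np.asarray(theta_free, dtype=float)
    if theta_free.size != len(free_names):
        raise ContractError(
            f"{theta_free.size} values supplied for {len(free_names)} free parameters"
        )
    return base.replace(**dict(zip(free_names, theta_free)))


def residual_vector(
    theta_free,
    dataset: PVDataset,
    free_names=None,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
) -> np.ndarray:
    """Stacked residuals (data − model) over V_lv, P_lv, P_ao.

    Simulation failure returns a flat sentinel vector whose squared norm
    is :data:`SENTINEL_COST` (with a logged warning) rather than raising,
    so optimization can route around pathological parameter sets.
    """
    from .model import DEFAULT_FREE

    data = dataset.stacked()
    free_names = tuple(free_names or DEFAULT_FREE)
    params = _assemble(theta_free, free_names, base_params or ModelParameters())
    try:
        params.validate(constants or ModelConstants())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = stacked_output(params, constants, dataset.sampling_rate)
    except (ContractError, FloatingPointError) as exc:
        log.warning("forward solve failed (%s); sentinel residuals used", exc)
        return np.full(data.size, np.sqrt(SENTINEL_COST / data.size))
    return data - model


def cost_ols(theta_free, dataset, free_names=None, base_params=None, constants=None) -> float:
    """Sum-of-squares calibration cost J(θ) ≥ 0."""
    r = residual_vector(theta_free, dataset, free_names, base_params, constants)
    return float(r @ r)


@dataclass
class MultistartResult:
    """Outcome of a seeded multistart optimization, sorted by cost."""

    free_names: tuple[str, ...]
    estimates: np.ndarray  # (n_starts, p), cost-ascending
    costs: np.ndarray  # (n_starts,)
    starts: np.ndarray  # initial points in the sorted order
    bounds: tuple[np.ndarray, np.ndarray]
    n_starts: int
    seed: int
    base_params: ModelParameters

    @property
    def theta_hat(self) -> np.ndarray:
        return self.estimates[0]

    @property
    def best_cost(self) -> float:
        return float(self.costs[0])

    @property
    def best_params(self) -> ModelParameters:
        return _assemble(self.theta_hat, self.free_names, self.base_params)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.estimates, columns=list(self.free_names))
        frame.insert(0, "cost", self.costs)
        return frame


def bounds_for(free_names, overrides: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Default optimization bounds (a priori parameter ranges) for a subset."""
    table = dict(_BOUNDS_WITH_RAV, **(overrides or {}))
    lo = np.array([table[n][0] for n in free_names])
    hi = np.array([table[n][1] for n in free_names])
    if np.any(lo >= hi):
        raise ContractError("bounds must satisfy lower < upper")
    return lo, hi


def multistart_fit(
    dataset: PVDataset,
    free_names=None,
    bounds: dict | None = None,
    n_starts: int = 100,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
    max_nfev: int = 2000,
) -> MultistartResult:
    """Bounded local least-squares from ``n_starts`` uniform random
    initial points; deterministic given ``seed``.

    Each start is refined with a trust-region-reflective least-squares
    solver honouring the box bounds; results are returned sorted by cost.
    """
    from .model import DEFAULT_FREE

    free_names = tuple(free_names or DEFAULT_FREE)
    base = base_params or ModelParameters()
    lo, hi = bounds_for(free_names, bounds)
    rng = np.random.default_rng(seed)
    starts = np.empty((n_starts, len(free_names)))
    for i in range(n_starts):
        # uniform draw over the valid region: reject draws that violate the
        # ordering invariants (e.g. e_es > e_ed), which simulate nothing
        for _ in range(1000):
            draw = rng.uniform(lo, hi)
            try:
                _assemble(draw, free_names, base).validate(constants or ModelConstants())
            except ContractError:
                continue
            break
        starts[i] = draw
    estimates = np.empty_like(starts)
    costs = np.full(n_starts, np.inf)
    failures = []
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                residual_vector,
                x0,
                bounds=(lo, hi),
                args=(dataset, free_names, base, constants),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=max_nfev,
            )
            estimates[i] = np.clip(sol.x, lo, hi)
            costs[i] = 2.0 * sol.cost  # scipy reports 0.5 * sum of squares
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append((i, repr(exc)))
            estimates[i] = x0
            costs[i] = np.inf
    if len(failures) == n_starts:
        raise RuntimeError(f"all {n_starts} starts failed: {failures}")
    order = np.argsort(costs, kind="stable")
    return MultistartResult(
        free_names=free_names,
        estimates=estimates[order],
        costs=costs[order],
        starts=starts[order],
        bounds=(lo, hi),
        n_starts=n_starts,
        seed=seed,
        base_params=base,
    )


def top_k_cov(result: MultistartResult, k: int = 20) -> dict[str, float]:
    """Coefficient of variation (%) of each free parameter over the ``k``
    lowest-cost estimates — a practical-identifiability summary."""
    if k > result.n_starts:
        raise ContractError("k cannot exceed the number of starts")
    top = result.estimates[:k]
    mean = top.mean(axis=0)
    if np.any(mean == 0):
        raise ContractError("top-k mean of zero; CoV undefined")
    cov = 100.0 * top.std(axis=0, ddof=1) / mean
    return dict(zip(result.free_names, np.abs(cov)))


def information_criteria(j_min: float, n_residuals: int, p_free: int) -> tuple[float, float]:
    """Gaussian-likelihood AIC and BIC (constant terms dropped).

    AIC = n·ln(J/n) + 2(p+1) and BIC = n·ln(J/n) + ln(n)·(p+1); the noise
    variance counts as one estimated parameter.
    """
    if j_min <= 0:
        raise ContractError("information criteria need J_min > 0")
    if n_residuals <= p_free:
        raise ContractError("need more residuals than free parameters")
    n, p = n_residuals, p_free
    gof = n * np.log(j_min / n)
    return float(gof + 2 * (p + 1)), float(gof + np.log(n) * (p + 1))


@dataclass
class SubsetComparison:
    """AIC/BIC comparison of nested free-parameter subsets."""

    table: pd.DataFrame  # sorted by AIC
    results: dict[tuple[str, ...], MultistartResult]

    @property
    def best_subset(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["free_names"])


def compare_subsets(
    dataset: PVDataset,
    subsets,
    n_starts: int = 100,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
    max_nfev: int = 2000,
) -> SubsetComparison:
    """One multistart per candidate subset (non-members fixed at their
    a priori values); rows sorted by AIC, smaller is better."""
    rows, results = [], {}
    n = 3 * dataset.n_samples
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ContractError("subsets must be nonempty")
        res = multistart_fit(
            dataset,
            subset,
            n_starts=n_starts,
            seed=seed,
            base_params=base_params,
            constants=constants,
            max_nfev=max_nfev,
        )
        aic, bic = information_criteria(res.best_cost, n, len(subset))
        results[subset] = res
        rows.append(
            {
                "free_names": subset,
                "p_free": len(subset),
                "cost": res.best_cost,
                "n_residuals": n,
                "AIC": aic,
                "BIC": bic,
            }
        )
    table = pd.DataFrame(rows).sort_values("AIC", ignore_index=True)
    return SubsetComparison(table=table, results=results)
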