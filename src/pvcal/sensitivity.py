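"""Local sensitivity analysis, parameter ranking, correlation-based
subset selection, and profile-likelihood identifiability.

Sensitivities are central-difference derivatives of the three simulated
signals with respect to each parameter.  Entries are made dimensionless
by relative parameter scaling and by dividing each signal by the mean of
the corresponding data source, so the scalar ranking ∑ S² is comparable
across parameters with units as different as mmHg·s/µL and µL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .data import PVDataset, SIGNAL_NAMES
from .frequentist import cost_ols
from .model import (
    PARAM_NAMES,
    ContractError,
    ModelConstants,
    ModelParameters,
    beat_summary,
    simulate_to_steady_beat,
    stacked_output,
)

__all__ = [
    "SensitivityMatrix",
    "ProfileCurve",
    "central_difference_jacobian",
    "tornado_analysis",
    "local_sensitivity_matrix",
    "influence_ranking",
    "parameter_correlation_matrix",
    "select_subset",
    "profile_objective",
    "profile_likelihood",
]


def central_difference_jacobian(func, theta, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Jacobian of a vector-valued ``func`` with a step
    relative to each coordinate's magnitude."""
    theta = np.asarray(theta, dtype=float)
    y0 = np.asarray(func(theta), dtype=float)
    jac = np.empty((y0.size, theta.size))
    for i, th in enumerate(theta):
        h = rel_step * max(abs(th), rel_step)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        jac[:, i] = (np.asarray(func(up)) - np.asarray(func(dn))) / (2.0 * h)
    if not np.all(np.isfinite(jac)):
        bad = np.argwhere(~np.isfinite(jac))
        raise FloatingPointError(
            f"non-finite derivative at output row {bad[0][0]}, parameter index {bad[0][1]}"
        )
    return jac


@dataclass
class SensitivityMatrix:
    """Scaled sensitivities S (rows: stacked V_lv/P_lv/P_ao samples) plus
    the unscaled derivative matrix F for downstream covariance work."""

    S: np.ndarray  # (3n, p) dimensionless
    F: np.ndarray  # (3n, p) output units per parameter unit
    param_names: tuple[str, ...]
    signal_means: dict[str, float]
    time: np.ndarray

    def block(self, signal: str) -> np.ndarray:
        n = self.time.size
        i = SIGNAL_NAMES.index(signal)
        return self.S[i * n : (i + 1) * n]


def local_sensitivity_matrix(
    params: ModelParameters,
    dataset: PVDataset,
    h: float = 1e-4,
    free_names=PARAM_NAMES,
    constants: ModelConstants | None = None,
) -> SensitivityMatrix:
    """Central differences of the model output at ``params``.

    Scaled entry: S_{k,i}(t) = (∂y_k(t)/∂θ_i) · θ_i / ȳ_k with ȳ_k the
    mean of data signal k; relative parameter steps of ``h``.
    """
    free_names = tuple(free_names)
    base = params.to_array()
    idx = [PARAM_NAMES.index(n) for n in free_names]

    def forward(theta_free):
        full = base.copy()
        full[idx] = theta_free
        return stacked_output(ModelParameters.from_array(full), constants, dataset.sampling_rate)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        F = central_difference_jacobian(forward, base[idx], rel_step=h)
    n = dataset.n_samples
    means = {s: float(np.mean(getattr(dataset, s))) for s in SIGNAL_NAMES}
    scale_rows = np.concatenate([np.full(n, 1.0 / means[s]) for s in SIGNAL_NAMES])
    S = F * base[idx][np.newaxis, :] * scale_rows[:, np.newaxis]
    return SensitivityMatrix(
        S=S, F=F, param_names=free_names, signal_means=means, time=dataset.time.copy()
    )


def influence_ranking(sens: SensitivityMatrix) -> dict[str, float]:
    """Per-parameter influence score ∑_{t,k} S², descending."""
    scores = np.sum(sens.S**2, axis=0)
    order = np.argsort(-scores, kind="stable")
    return {sens.param_names[i]: float(scores[i]) for i in order}


def parameter_correlation_matrix(sens: SensitivityMatrix) -> pd.DataFrame:
    """Approximate parameter correlation from the sensitivity-based
    covariance proxy C = (SᵀS)⁺; entries in [−1, 1], unit diagonal."""
    S = sens.S
    p = S.shape[1]
    if p < 2:
        raise ContractError("need at least two parameters for correlations")
    if S.shape[0] < p:
        raise ContractError("fewer output rows than parameters")
    gram = S.T @ S
    if np.linalg.cond(gram) > 1e12:
        warnings.warn(
            "sensitivity Gram matrix is near-singular (condition number > 1e12); "
            "correlations from the pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    C = np.linalg.pinv(gram)
    d = np.sqrt(np.diag(C))
    corr = C / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=sens.param_names, columns=sens.param_names)


def select_subset(
    ranking: dict[str, float],
    correlations: pd.DataFrame,
    rank_floor: float = 1e-3,
    corr_cut: float = 0.95,
) -> tuple[list[str], dict[str, str]]:
    """Choose the free calibration subset.

    Parameters scoring below ``rank_floor`` × the top score are fixed as
    noninfluential; for each pair correlated beyond ``corr_cut`` the
    lower-ranked member is fixed.  Ties break on canonical parameter
    order, so the selection is deterministic.
    """
    names = list(ranking)
    top = max(ranking.values())
    fixed: dict[str, str] = {}
    for name in names:
        if ranking[name] < rank_floor * top:
            fixed[name] = f"noninfluential (score < {rank_floor:g} of max)"
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in fixed or b in fixed:
                continue
            c = abs(float(correlations.loc[a, b]))
            if c > corr_cut:
                lower = b if ranking[a] >= ranking[b] else a
                higher = a if lower == b else b
                fixed[lower] = f"correlated (|corr|={c:.3f}) with higher-ranked {higher}"
    free = [n for n in names if n not in fixed]
    if not free:
        raise ContractError("subset selection fixed every parameter")
    return free, fixed


def tornado_analysis(
    params: ModelParameters,
    constants: ModelConstants | None = None,
    delta: float = 0.10,
    free_names=PARAM_NAMES,
    sampling_rate: float = 500.0,
) -> pd.DataFrame:
    """One-at-a-time ±``delta`` parameter screening.

    Reports the percent change of each systolic/diastolic summary output
    (max/min of P_lv, V_lv, P_ao) when each parameter is raised and
    lowered by the given fraction; failed perturbations yield NaN rows
    flagged in the ``failed`` column.
    """
    outputs = ("max_p_lv", "min_p_lv", "max_v_lv", "min_v_lv", "max_p_ao", "min_p_ao")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = beat_summary(simulate_to_steady_beat(params, constants, sampling_rate=sampling_rate))
    rows = []
    for name in free_names:
        row: dict[str, object] = {"parameter": name}
        for sign, label in ((1.0, "plus"), (-1.0, "minus")):
            perturbed = params.replace(**{name: getattr(params, name) * (1.0 + sign * delta)})
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    summ = beat_summary(
                        simulate_to_steady_beat(perturbed, constants, sampling_rate=sampling_rate)
                    )
                for out in outputs:
                    row[f"{out}_{label}_pct"] = 100.0 * (summ[out] - base[out]) / base[out]
                row.setdefault("failed", False)
            except (FloatingPointError, ContractError):
                for out in outputs:
                    row[f"{out}_{label}_pct"] = np.nan
                row["failed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ProfileCurve:
    """Profile-likelihood sweep of one parameter.

    classification: 'identifiable' if the re-optimized cost crosses the
    threshold on both sides of the minimum, 'one_sided' if on one side
    only, 'flat' if never.
    """

    parameter: str
    grid: np.ndarray
    costs: np.ndarray
    threshold: float
    cost_min: float
    classification: str


def _classify(grid, costs, threshold, cost_min) -> str:
    i_min = int(np.argmin(costs))
    left = np.any(costs[: i_min + 1] > threshold)
    right = np.any(costs[i_min:] > threshold)
    if left and right:
        return "identifiable"
    if left or right:
        return "one_sided"
    return "flat"


def profile_objective(
    objective,
    theta_hat,
    bounds,
    index: int,
    grid,
    n_obs: int,
    alpha: float = 0.05,
) -> ProfileCurve:
    """Generic profile-likelihood engine.

    At each grid value of coordinate ``index`` the remaining coordinates
    are re-optimized (warm-started along the sweep).  The threshold is the
    Gaussian-approximation cost ratio J*·(1 + χ²_{1−α,1}/(n−p)).
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ContractError("profile grid must be strictly increasing")
    if not (grid[0] <= theta_hat[index] <= grid[-1]):
        warnings.warn("profile grid does not bracket the estimate", RuntimeWarning, stacklevel=2)
    p = theta_hat.size
    others = [i for i in range(p) if i != index]
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)

    cost_min = float(objective(theta_hat))
    threshold = cost_min * (1.0 + chi2.ppf(1.0 - alpha, df=1) / max(n_obs - p, 1))

    costs = np.empty(grid.size)
    warm = theta_hat[others].copy()
    for j, value in enumerate(grid):
        if not others:
            full = theta_hat.copy()
            full[index] = value
            costs[j] = float(objective(full))
            continue

        def reduced(x):
            full = theta_hat.copy()
            full[index] = value
            full[others] = x
            return float(objective(full))

        sol = minimize(
            reduced,
            np.clip(warm, lo[others], hi[others]),
            method="L-BFGS-B",
            bounds=list(zip(lo[others], hi[others])),
        )
        warm = sol.x
        costs[j] = float(sol.fun)
    return ProfileCurve(
        parameter=str(index),
        grid=grid,
        costs=costs,
        threshold=threshold,
        cost_min=cost_min,
        classification=_classify(grid, costs, threshold, cost_min),
    )


def profile_likelihood(
    dataset: PVDataset,
    free_names,
    target: str,
    grid,
    theta_hat=None,
    alpha: float = 0.05,
    base_params: ModelParameters | None = None,
    constants: ModelConstants | None = None,
    bounds: dict | None = None,
) -> ProfileCurve:
    """Profile the calibration cost along ``target``, re-optimizing the
    remaining free parameters at each grid point."""
    from .frequentist import bounds_for, multistart_fit

    free_names = tuple(free_names)
    if target not in free_names:
        raise ContractError(f"target {target!r} not in the free subset")
    if theta_hat is None:
        theta_hat = multistart_fit(
            dataset, free_names, n_starts=10, seed=0, base_params=base_params, constants=constants
        ).theta_hat
    lo, hi = bounds_for(free_names, bounds)
    index = free_names.index(target)

    def objective(theta):
        return cost_ols(theta, dataset, free_names, base_params, constants)

    curve = profile_objective(
        objective,
        theta_hat,
        list(zip(lo, hi)),
        index,
        grid,
        n_obs=3 * dataset.n_samples,
        alpha=alpha,
    )
    curve.parameter = target
    return curve
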