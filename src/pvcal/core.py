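"""Model/Results interface tying the toolkit together.

:class:`PVModel` wraps a pressure--volume dataset together with the
circuit constants, the free-parameter subset and its bounds.  ``fit()``
runs the multistart least-squares calibration and returns a
:class:`FrequentistPVResults`; ``fit_bayes()`` runs adaptive Metropolis
and returns a :class:`BayesianPVResults`.  Both results objects carry
estimates, uncertainties, diagnostics and a ``summary()`` table, with
simulation and band construction hanging off them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayesian, frequentist, sensitivity, uq
from .data import PVDataset, read_pv_csv
from .model import (
    DEFAULT_FREE,
    ContractError,
    ModelConstants,
    ModelParameters,
    beat_summary,
    simulate_to_steady_beat,
)

__all__ = ["PVModel", "FrequentistPVResults", "BayesianPVResults"]


class PVModel:
    """Lumped-parameter LV--aorta model bound to one dataset.

    Parameters
    ----------
    dataset : PVDataset
        One averaged beat of V_lv, P_lv and P_ao samples.
    free_names : sequence of str, optional
        Parameters to calibrate (default: the seven-parameter subset with
        the aortic valve resistance and dead volume fixed).
    base_params : ModelParameters, optional
        Values for fixed parameters and calibration anchors (default: the
        a priori set).
    """

    def __init__(
        self,
        dataset: PVDataset,
        free_names=DEFAULT_FREE,
        base_params: ModelParameters | None = None,
        constants: ModelConstants | None = None,
        bounds: dict | None = None,
    ):
        self.dataset = dataset
        self.free_names = tuple(free_names)
        self.base_params = base_params or ModelParameters()
        self.constants = constants or ModelConstants()
        self.bounds = bounds

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_csv(cls, path, **kwargs) -> "PVModel":
        return cls(read_pv_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, sampling_rate=500.0, t_cycle=0.11, **kwargs):
        ds = PVDataset(
            time=frame["time"].to_numpy(),
            v_lv=frame["V_LV"].to_numpy(),
            p_lv=frame["P_LV"].to_numpy(),
            p_ao=frame["P_Ao"].to_numpy(),
            sampling_rate=sampling_rate,
            t_cycle=t_cycle,
        )
        return cls(ds, **kwargs)

    # -- forward problem --------------------------------------------------
    def simulate(self, params: ModelParameters | None = None, **kwargs):
        return simulate_to_steady_beat(
            params or self.base_params,
            self.constants,
            sampling_rate=self.dataset.sampling_rate,
            **kwargs,
        )

    # -- analysis stages --------------------------------------------------
    def tornado(self, params=None, delta: float = 0.10):
        return sensitivity.tornado_analysis(
            params or self.base_params,
            self.constants,
            delta=delta,
            sampling_rate=self.dataset.sampling_rate,
        )

    def sensitivity(self, params=None, h: float = 1e-4, free_names=None):
        return sensitivity.local_sensitivity_matrix(
            params or self.base_params,
            self.dataset,
            h=h,
            free_names=free_names or self.free_names,
            constants=self.constants,
        )

    def select_subset(self, rank_floor=1e-3, corr_cut=0.95, free_names=None):
        from .model import PARAM_NAMES

        sens = self.sensitivity(free_names=free_names or PARAM_NAMES)
        ranking = sensitivity.influence_ranking(sens)
        corr = sensitivity.parameter_correlation_matrix(sens)
        return sensitivity.select_subset(ranking, corr, rank_floor, corr_cut)

    def cost(self, theta_free):
        return frequentist.cost_ols(
            theta_free, self.dataset, self.free_names, self.base_params, self.constants
        )

    def fit(self, n_starts: int = 100, seed: int = 0, max_nfev: int = 2000):
        """Multistart bounded least squares → :class:`FrequentistPVResults`."""
        ms = frequentist.multistart_fit(
            self.dataset,
            self.free_names,
            bounds=self.bounds,
            n_starts=n_starts,
            seed=seed,
            base_params=self.base_params,
            constants=self.constants,
            max_nfev=max_nfev,
        )
        return FrequentistPVResults(model=self, multistart=ms)

    def fit_bayes(self, n_iter: int = 100_000, seed: int = 0, **kwargs):
        """Adaptive Metropolis MCMC → :class:`BayesianPVResults`."""
        priors = bayesian.PriorSpec.from_defaults(self.free_names)
        if self.bounds:
            priors = bayesian.PriorSpec({**priors.bounds, **self.bounds})
        chain = bayesian.adaptive_metropolis_sample(
            self.dataset,
            priors,
            n_iter=n_iter,
            seed=seed,
            base_params=self.base_params,
            constants=self.constants,
            **kwargs,
        )
        return BayesianPVResults(model=self, chain=chain)

    def profile(self, target: str, grid, theta_hat=None, alpha=0.05):
        return sensitivity.profile_likelihood(
            self.dataset,
            self.free_names,
            target,
            grid,
            theta_hat=theta_hat,
            alpha=alpha,
            base_params=self.base_params,
            constants=self.constants,
            bounds=self.bounds,
        )


@dataclass
class FrequentistPVResults:
    """Multistart OLS estimates with asymptotic uncertainty."""

    model: PVModel
    multistart: frequentist.MultistartResult
    _ci_cache: tuple | None = field(default=None, repr=False)

    @property
    def theta_hat(self) -> np.ndarray:
        return self.multistart.theta_hat

    @property
    def params(self) -> ModelParameters:
        return self.multistart.best_params

    @property
    def cost(self) -> float:
        return self.multistart.best_cost

    @property
    def n_residuals(self) -> int:
        return 3 * self.model.dataset.n_samples

    def _ci(self, alpha=0.05):
        if self._ci_cache is None or self._ci_cache[0] != alpha:
            table, cov, s2 = uq.asymptotic_parameter_ci(
                self.theta_hat,
                self.model.dataset,
                self.model.free_names,
                self.model.base_params,
                self.model.constants,
                alpha=alpha,
            )
            self._ci_cache = (alpha, table, cov, s2)
        return self._ci_cache

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._ci(alpha)[1]

    @property
    def cov_params(self) -> np.ndarray:
        return self._ci()[2]

    @property
    def sigma2_hat(self) -> float:
        return self._ci()[3]

    def cov_of_variation(self, k: int = 20) -> dict[str, float]:
        return frequentist.top_k_cov(self.multistart, k=min(k, self.multistart.n_starts))

    def information_criteria(self) -> tuple[float, float]:
        return frequentist.information_criteria(
            self.cost, self.n_residuals, len(self.model.free_names)
        )

    def output_bands(self, alpha: float = 0.05):
        return uq.frequentist_output_bands(
            self.theta_hat,
            self.model.dataset,
            self.model.free_names,
            self.model.base_params,
            self.model.constants,
            alpha=alpha,
        )

    def residual_diagnostics(self, alpha: float = 0.05):
        return uq.residual_diagnostics(
            self.theta_hat,
            self.model.dataset,
            self.model.free_names,
            self.model.base_params,
            self.model.constants,
            alpha=alpha,
        )

    def simulate(self):
        return self.model.simulate(self.params)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        table = self.conf_int(alpha).copy()
        cov = self.cov_of_variation()
        table["cov_top20_pct"] = [cov[n] for n in table.index]
        aic, bic = self.information_criteria()
        table.attrs.update(
            cost=self.cost, AIC=aic, BIC=bic, sigma2_hat=self.sigma2_hat,
            n_starts=self.multistart.n_starts, seed=self.multistart.seed,
        )
        return table


@dataclass
class BayesianPVResults:
    """Posterior chain with summaries, diagnostics and output bands."""

    model: PVModel
    chain: bayesian.PosteriorChain

    @property
    def map_params(self) -> ModelParameters:
        theta = self.chain.map_sample()
        return self.model.base_params.replace(**dict(zip(self.chain.names, theta)))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return bayesian.posterior_summary(self.chain, level=level)

    def diagnostics(self) -> pd.DataFrame:
        return bayesian.chain_diagnostics(self.chain)

    def output_bands(self, n_draws: int = 2000, alpha: float = 0.05, seed: int = 0):
        return uq.bayesian_output_bands(
            self.chain,
            self.model.dataset,
            n_draws=n_draws,
            alpha=alpha,
            base_params=self.model.base_params,
            constants=self.model.constants,
            seed=seed,
        )

    def simulate(self):
        return self.model.simulate(self.map_params)
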