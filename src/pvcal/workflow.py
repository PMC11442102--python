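"""Configuration-driven analysis pipeline.

Chains the stages simulate → sensitivity → subset selection → frequentist
fit → MCMC → uncertainty quantification over a JSON configuration, writing
every stage artifact as CSV/JSON plus a provenance record (config hash,
seeds, package versions, ISO timestamps) so any stage can be re-run from
its persisted inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import PVModel
from .data import NoiseSpec, PVDataset, read_pv_csv, synthesize_dataset, write_pv_csv
from .model import (
    DEFAULT_BOUNDS,
    DEFAULT_FREE,
    PARAM_NAMES,
    ContractError,
    ModelConstants,
    ModelParameters,
)
from . import sensitivity as sens_mod
from . import frequentist as freq_mod

__all__ = ["WorkflowConfig", "load_config", "save_config", "run_workflow", "PROFILES"]

log = logging.getLogger("pvcal.workflow")

ALL_STAGES = ("simulate", "sens", "subset", "fit", "mcmc", "uq")

#: Reduced settings for quick runs vs. the full reference analysis.
PROFILES = {
    "test": {"n_starts": 10, "n_iter": 5000, "n_draws": 200},
    "paper": {"n_starts": 100, "n_iter": 100_000, "n_draws": 2000},
}

_KNOWN_KEYS = {
    "data",
    "synthetic",
    "constants",
    "parameters",
    "ranges",
    "stages",
    "seed",
    "profile",
    "out_dir",
    "n_starts",
    "n_iter",
    "n_draws",
    "free_names",
    "sampling_rate",
}


@dataclass
class WorkflowConfig:
    """Validated workflow settings with all defaults filled."""

    data: str | None = None
    synthetic: dict = field(default_factory=dict)
    constants: ModelConstants = field(default_factory=ModelConstants)
    parameters: ModelParameters = field(default_factory=ModelParameters)
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    profile: str = "test"
    out_dir: str = "pvcal_run"
    n_starts: int | None = None
    n_iter: int | None = None
    n_draws: int | None = None
    free_names: tuple[str, ...] = DEFAULT_FREE
    sampling_rate: float = 500.0

    def resolved(self, key: str) -> int:
        value = getattr(self, {"n_starts": "n_starts", "n_iter": "n_iter", "n_draws": "n_draws"}[key])
        return value if value is not None else PROFILES[self.profile][key]

    def to_dict(self) -> dict:
        return {
            "data": self.data,
            "synthetic": self.synthetic,
            "constants": asdict(self.constants),
            "parameters": asdict(self.parameters),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "stages": list(self.stages),
            "seed": self.seed,
            "profile": self.profile,
            "out_dir": self.out_dir,
            "n_starts": self.n_starts,
            "n_iter": self.n_iter,
            "n_draws": self.n_draws,
            "free_names": list(self.free_names),
            "sampling_rate": self.sampling_rate,
        }


def _validate(raw: dict, path: str) -> WorkflowConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ContractError(f"unknown config key(s) {sorted(unknown)} in {path}")
    constants = ModelConstants(**raw.get("constants", {}))
    parameters = ModelParameters(**raw.get("parameters", {}))
    ranges = dict(DEFAULT_BOUNDS)
    for name, pair in raw.get("ranges", {}).items():
        if name not in PARAM_NAMES:
            raise ContractError(f"range given for unknown parameter {name!r}")
        lo, hi = float(pair[0]), float(pair[1])
        if not lo < hi:
            raise ContractError(f"range for {name!r} must have lower < upper")
        ranges[name] = (lo, hi)
    stages = tuple(raw.get("stages", ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            raise ContractError(f"unknown stage {s!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ContractError("seed must be an integer")
    profile = raw.get("profile", "test")
    if profile not in PROFILES:
        raise ContractError(f"unknown profile {profile!r}")
    data = raw.get("data")
    if data is not None and not Path(data).exists():
        raise ContractError(f"data file {data!r} does not exist")
    free = tuple(raw.get("free_names", DEFAULT_FREE))
    for name in free:
        if name not in PARAM_NAMES:
            raise ContractError(f"unknown free parameter {name!r}")
    return WorkflowConfig(
        data=data,
        synthetic=raw.get("synthetic", {}),
        constants=constants,
        parameters=parameters,
        ranges=ranges,
        stages=stages,
        seed=seed,
        profile=profile,
        out_dir=raw.get("out_dir", "pvcal_run"),
        n_starts=raw.get("n_starts"),
        n_iter=raw.get("n_iter"),
        n_draws=raw.get("n_draws"),
        free_names=free,
        sampling_rate=float(raw.get("sampling_rate", 500.0)),
    )


def load_config(path) -> WorkflowConfig:
    """Load and validate a JSON workflow configuration; an empty file
    body (``{}``) yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise ContractError(f"config file {path} not found")
    raw = json.loads(path.read_text())
    return _validate(raw, str(path))


def save_config(config: WorkflowConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))


def _config_hash(config: WorkflowConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def _load_dataset(config: WorkflowConfig, out_dir: Path) -> PVDataset:
    if config.data is not None:
        return read_pv_csv(config.data)
    spec = dict(config.synthetic)
    noise = NoiseSpec(
        kind=spec.get("kind", "iid"),
        sigma=float(spec.get("sigma", 2.0)),
        gamma=float(spec.get("gamma", 0.0)),
        rho=float(spec.get("rho", 0.0)),
        seed=int(spec.get("seed", config.seed)),
    )
    noisy, truth = synthesize_dataset(
        config.parameters, config.constants, noise, config.sampling_rate
    )
    write_pv_csv(noisy, out_dir / "synthetic_data.csv")
    write_pv_csv(truth, out_dir / "synthetic_truth.csv")
    return noisy


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the configured stages in order; returns the report bundle.

    Stage failures raise with the stage name; artifacts written before
    the failure are preserved in ``out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    t_start = time.time()
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "pvcal_version": __version__,
            "numpy_version": np.__version__,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stages_run": [],
    }
    save_config(config, out_dir / "config.json")

    stage = "load-data"
    try:
        dataset = _load_dataset(config, out_dir)
        model = PVModel(
            dataset,
            free_names=config.free_names,
            base_params=config.parameters,
            constants=config.constants,
            bounds={k: config.ranges[k] for k in config.free_names if k in config.ranges},
        )
        fit_result = None
        chain_result = None
        for stage in config.stages:
            log.info("stage %s", stage)
            if stage == "simulate":
                beat = model.simulate()
                beat.to_csv(out_dir / "beat.csv")
                report["simulate"] = {
                    "n_beats_to_converge": beat.n_beats_to_converge,
                    "convergence_metric": beat.convergence_metric,
                }
            elif stage == "sens":
                tornado = model.tornado()
                tornado.to_csv(out_dir / "tornado.csv", index=False)
                sens = model.sensitivity(free_names=PARAM_NAMES)
                ranking = sens_mod.influence_ranking(sens)
                corr = sens_mod.parameter_correlation_matrix(sens)
                pd.DataFrame(sens.S, columns=sens.param_names).to_csv(
                    out_dir / "sensitivity_scaled.csv", index=False
                )
                corr.to_csv(out_dir / "parameter_correlations.csv")
                pd.Series(ranking).to_csv(out_dir / "influence_ranking.csv")
                report["sens"] = {"ranking": ranking}
                report["_corr"] = corr
                report["_ranking"] = ranking
            elif stage == "subset":
                if "_ranking" not in report:
                    sens = model.sensitivity(free_names=PARAM_NAMES)
                    report["_ranking"] = sens_mod.influence_ranking(sens)
                    report["_corr"] = sens_mod.parameter_correlation_matrix(sens)
                free, fixed = sens_mod.select_subset(report["_ranking"], report["_corr"])
                report["subset"] = {"free": free, "fixed": fixed}
                (out_dir / "subset.json").write_text(
                    json.dumps({"free": free, "fixed": fixed}, indent=2)
                )
                model.free_names = tuple(free)
                model.bounds = {
                    k: config.ranges[k] for k in model.free_names if k in config.ranges
                }
            elif stage == "fit":
                fit_result = model.fit(n_starts=config.resolved("n_starts"), seed=config.seed)
                summary = fit_result.summary()
                summary.to_csv(out_dir / "fit_summary.csv")
                fit_result.multistart.to_frame().to_csv(out_dir / "multistart.csv", index=False)
                aic, bic = fit_result.information_criteria()
                report["fit"] = {
                    "theta_hat": dict(zip(model.free_names, fit_result.theta_hat)),
                    "cost": fit_result.cost,
                    "AIC": aic,
                    "BIC": bic,
                    "cov_top_k_pct": fit_result.cov_of_variation(),
                }
            elif stage == "mcmc":
                result = model.fit_bayes(n_iter=config.resolved("n_iter"), seed=config.seed)
                chain_result = result
                result.chain.to_frame().to_csv(out_dir / "chain.csv", index=False)
                result.summary().to_csv(out_dir / "posterior_summary.csv")
                result.diagnostics().to_csv(out_dir / "chain_diagnostics.csv")
                report["mcmc"] = {
                    "acceptance_rate": result.chain.acceptance_rate,
                    "n_iter": result.chain.n_iter,
                }
            elif stage == "uq":
                if fit_result is not None:
                    for sig, band in fit_result.output_bands().items():
                        band.to_frame().to_csv(out_dir / f"freq_bands_{sig}.csv", index=False)
                    diag = fit_result.residual_diagnostics()
                    (out_dir / "residual_diagnostics.json").write_text(
                        json.dumps(
                            {
                                s: {
                                    k: v
                                    for k, v in d.items()
                                    if np.isscalar(v) or isinstance(v, (bool, dict))
                                }
                                for s, d in diag.items()
                            },
                            indent=2,
                            default=str,
                        )
                    )
                    report["uq"] = {
                        "iid_verdicts": {s: bool(d["iid"]) for s, d in diag.items()}
                    }
                if chain_result is not None:
                    bands = chain_result.output_bands(
                        n_draws=min(
                            config.resolved("n_draws"),
                            chain_result.chain.n_iter - chain_result.chain.burn_in,
                        )
                    )
                    for sig, band in bands.items():
                        band.to_frame().to_csv(out_dir / f"bayes_bands_{sig}.csv", index=False)
            report["stages_run"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"workflow stage {stage!r} failed: {exc}") from exc
    report.pop("_corr", None)
    report.pop("_ranking", None)
    report["provenance"]["elapsed_s"] = time.time() - t_start
    report["provenance"]["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
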