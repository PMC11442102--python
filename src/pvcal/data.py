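"""Pressure--volume datasets, beat averaging, a priori parameter rules and
synthetic data generation with three measurement-error models.

A :class:`PVDataset` is one cardiac cycle of aligned LV volume, LV
pressure and aortic pressure samples on a uniform grid, mirroring the
structure of an averaged-beat murine pressure--volume recording (500 Hz,
0.11 s cycle, 55 samples with the endpoint excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    BeatSeries,
    ContractError,
    ModelConstants,
    ModelParameters,
    beat_summary,
    simulate_to_steady_beat,
)

__all__ = [
    "PVDataset",
    "NoiseSpec",
    "read_pv_csv",
    "write_pv_csv",
    "average_beats",
    "apriori_parameters",
    "synthesize_dataset",
    "quadratic_testbed",
]

CSV_COLUMNS = ("time", "V_LV", "P_LV", "P_Ao")
SIGNAL_NAMES = ("v_lv", "p_lv", "p_ao")


@dataclass
class PVDataset:
    """One beat of volume (µL) and pressure (mmHg) measurements."""

    time: np.ndarray
    v_lv: np.ndarray
    p_lv: np.ndarray
    p_ao: np.ndarray
    sampling_rate: float = 500.0
    t_cycle: float = 0.11

    def __post_init__(self) -> None:
        for name in ("time", *SIGNAL_NAMES):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if any(getattr(self, s).size != n for s in SIGNAL_NAMES):
            raise ContractError("PVDataset vectors must have equal length")
        if n != int(round(self.sampling_rate * self.t_cycle)):
            raise ContractError(
                "PVDataset length must equal round(sampling_rate * t_cycle)"
            )
        if n > 1:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ContractError("PVDataset time grid must be uniform")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def signals(self) -> dict[str, np.ndarray]:
        return {s: getattr(self, s) for s in SIGNAL_NAMES}

    def stacked(self) -> np.ndarray:
        """Signals stacked in the canonical residual order (V, P_lv, P_ao)."""
        return np.concatenate([self.v_lv, self.p_lv, self.p_ao])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "V_LV": self.v_lv, "P_LV": self.p_lv, "P_Ao": self.p_ao}
        )

    @classmethod
    def from_beat(cls, beat: BeatSeries, sampling_rate: float, t_cycle: float) -> "PVDataset":
        return cls(
            time=beat.time.copy(),
            v_lv=beat.v_lv.copy(),
            p_lv=beat.p_lv.copy(),
            p_ao=beat.p_ao.copy(),
            sampling_rate=sampling_rate,
            t_cycle=t_cycle,
        )


def write_pv_csv(dataset: PVDataset, path) -> None:
    """Write a dataset as CSV with header ``time,V_LV,P_LV,P_Ao``."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_pv_csv(path, t_cycle: float | None = None) -> PVDataset:
    """Read a ``time,V_LV,P_LV,P_Ao`` CSV into a :class:`PVDataset`.

    The write→read round trip preserves values to better than 1e-12.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ContractError(f"could not parse PV CSV {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ContractError(f"PV CSV {path} is missing column(s) {missing}")
    time = frame["time"].to_numpy(dtype=float)
    if time.size < 2:
        raise ContractError("PV CSV must contain at least two samples")
    dt = np.diff(time)
    if np.any(np.abs(dt - dt[0]) > 1e-9):
        raise ContractError("PV CSV time grid is not uniform (tolerance 1e-9 s)")
    fs = 1.0 / dt[0]
    t_cycle = t_cycle if t_cycle is not None else time.size / fs
    return PVDataset(
        time=time,
        v_lv=frame["V_LV"].to_numpy(dtype=float),
        p_lv=frame["P_LV"].to_numpy(dtype=float),
        p_ao=frame["P_Ao"].to_numpy(dtype=float),
        sampling_rate=fs,
        t_cycle=t_cycle,
    )


def average_beats(
    signals: dict[str, np.ndarray],
    sampling_rate: float,
    t_cycle: float,
    n_beats: int,
) -> PVDataset:
    """Pointwise mean of the first ``n_beats`` aligned beats of a
    multi-beat recording (keys ``v_lv``, ``p_lv``, ``p_ao``)."""
    n = int(round(sampling_rate * t_cycle))
    need = n_beats * n
    averaged = {}
    for name in SIGNAL_NAMES:
        x = np.asarray(signals[name], dtype=float)
        if x.size < need:
            raise ContractError(
                f"signal {name!r} has {x.size} samples; "
                f"{need} required for {n_beats} beats"
            )
        averaged[name] = x[:need].reshape(n_beats, n).mean(axis=0)
    return PVDataset(
        time=np.arange(n) / sampling_rate,
        sampling_rate=sampling_rate,
        t_cycle=t_cycle,
        **averaged,
    )


def apriori_parameters(
    dataset: PVDataset,
    constants: ModelConstants | None = None,
    cardiac_output: float | None = None,
    r_mv: float = 5.0e-3,
    r_av: float = 1.0e-3,
    v_lv_d: float = 5.0,
    t_s: float | None = None,
    t_e: float | None = None,
) -> ModelParameters:
    """A priori parameter values from pressure--volume extrema.

    E_es = max(P_lv)/min(V_lv); E_ed = min(P_lv)/max(V_lv);
    R_art = (mean(P_ao) − P_cap)/CO with CO = stroke volume / cycle
    length unless supplied; C_ao = stroke volume / aortic pulse pressure.
    Valve resistances and the dead volume take small fixed defaults.
    Timing parameters default to the time of peak dP_lv/dt (T_s surrogate)
    and the start of diastole (T_e), with fallbacks 0.044 s and 0.077 s.
    """
    constants = constants or ModelConstants()
    sv = float(np.max(dataset.v_lv) - np.min(dataset.v_lv))
    pulse = float(np.max(dataset.p_ao) - np.min(dataset.p_ao))
    if sv <= 0 or pulse <= 0:
        raise ContractError("degenerate dataset: zero stroke volume or pulse pressure")
    if cardiac_output is None:
        cardiac_output = sv / dataset.t_cycle
    if cardiac_output <= 0:
        raise ContractError("cardiac output must be positive")
    if t_s is None or t_e is None:
        dpdt = np.gradient(dataset.p_lv, dataset.time)
        t_s_est = float(dataset.time[int(np.argmax(dpdt))])
        t_e_est = float(dataset.time[int(np.argmin(dpdt))])
        t_s = t_s if t_s is not None else (t_s_est if 0 < t_s_est else 4.40e-2)
        t_e = t_e if t_e is not None else (t_e_est if t_s < t_e_est < dataset.t_cycle else 7.70e-2)
        if not 0 < t_s < t_e < dataset.t_cycle:
            t_s, t_e = 4.40e-2, 7.70e-2
    return ModelParameters(
        r_mv=r_mv,
        r_av=r_av,
        r_art=(float(np.mean(dataset.p_ao)) - constants.p_cap) / cardiac_output,
        e_es=float(np.max(dataset.p_lv)) / float(np.min(dataset.v_lv)),
        e_ed=float(np.min(dataset.p_lv)) / float(np.max(dataset.v_lv)),
        t_s=t_s,
        t_e=t_e,
        v_lv_d=v_lv_d,
        c_ao=sv / pulse,
    )


@dataclass
class NoiseSpec:
    """Measurement-error model for synthetic data.

    kind : 'iid' (Gaussian, constant variance), 'heteroskedastic'
        (independent Gaussian with sd σ·(1 + γ·t)), or 'correlated'
        (stationary lag-1 autoregressive with coefficient ρ and marginal
        sd σ).
    sigma : baseline noise sd in each signal's own units.
    gamma : heteroskedastic growth rate (1/abscissa unit).
    rho : lag-1 correlation coefficient, |ρ| < 1.
    seed : RNG seed; generation is bit-reproducible given the seed.
    """

    kind: str = "iid"
    sigma: float = 1.0
    gamma: float = 0.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("iid", "heteroskedastic", "correlated"):
            raise ContractError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.gamma < 0 or not abs(self.rho) < 1:
            raise ContractError("require sigma >= 0, gamma >= 0, |rho| < 1")


def _noise_vector(spec: NoiseSpec, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = x.size
    if spec.sigma == 0:
        # still consume the draws so the stream is kind-independent
        rng.standard_normal(n)
        return np.zeros(n)
    z = rng.standard_normal(n)
    if spec.kind == "iid":
        return spec.sigma * z
    if spec.kind == "heteroskedastic":
        return spec.sigma * (1.0 + spec.gamma * x) * z
    # stationary AR(1) with marginal sd sigma
    eps = np.empty(n)
    eps[0] = spec.sigma * z[0]
    innov_sd = spec.sigma * np.sqrt(1.0 - spec.rho**2)
    for k in range(1, n):
        eps[k] = spec.rho * eps[k - 1] + innov_sd * z[k]
    return eps


def synthesize_dataset(
    params: ModelParameters,
    constants: ModelConstants | None = None,
    noise: NoiseSpec | None = None,
    sampling_rate: float = 500.0,
) -> tuple[PVDataset, PVDataset]:
    """Simulate a converged beat and overlay measurement noise.

    Returns ``(noisy, truth)``.  Each of the three signals receives an
    independent noise stream from a single seeded generator; with
    ``sigma = 0`` the noisy dataset equals the truth exactly.
    """
    constants = constants or ModelConstants()
    noise = noise or NoiseSpec(sigma=0.0)
    beat = simulate_to_steady_beat(params, constants, sampling_rate=sampling_rate)
    truth = PVDataset.from_beat(beat, sampling_rate, constants.t_cycle)
    rng = np.random.default_rng(noise.seed)
    noisy = {
        name: getattr(truth, name) + _noise_vector(noise, truth.time, rng)
        for name in SIGNAL_NAMES
    }
    return (
        PVDataset(
            time=truth.time.copy(),
            sampling_rate=sampling_rate,
            t_cycle=constants.t_cycle,
            **noisy,
        ),
        truth,
    )


def quadratic_testbed(
    x_grid: np.ndarray, noise: NoiseSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic error-model testbed M(x) = 0.4x² − 0.1x + 2.

    Returns ``(y_true, y_noisy)`` with noise applied over the abscissa
    exactly as :func:`synthesize_dataset` applies it over time.
    """
    x = np.asarray(x_grid, dtype=float)
    y_true = 0.4 * x**2 - 0.1 * x + 2.0
    if noise is None:
        return y_true, y_true.copy()
    rng = np.random.default_rng(noise.seed)
    return y_true, y_true + _noise_vector(noise, x, rng)
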