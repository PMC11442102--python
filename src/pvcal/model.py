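"""Lumped-parameter left-ventricle / aorta circuit model.

The heart--vessel system is reduced to a two-state circuit: a time-varying
linear-elastance left ventricle (LV) filled from a constant left-atrial
pressure source and ejecting through two diode valves into a single
compliant aortic compartment that drains through an arterial resistance
into a constant capillary pressure sink.  States are LV volume ``V_lv``
(µL) and aortic pressure ``P_ao`` (mmHg); everything else is algebraic.

Units follow small-rodent hemodynamics conventions: pressure mmHg, volume
µL, time s, resistance mmHg·s/µL, elastance mmHg/µL, compliance µL/mmHg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "ModelConstants",
    "ModelParameters",
    "BeatSeries",
    "elastance",
    "lv_pressure",
    "valve_flow",
    "rhs",
    "simulate_to_steady_beat",
    "beat_summary",
]

#: Canonical parameter order used by every array-facing routine.
PARAM_NAMES = (
    "r_mv",
    "r_av",
    "r_art",
    "e_es",
    "e_ed",
    "t_s",
    "t_e",
    "v_lv_d",
    "c_ao",
)


class ContractError(ValueError):
    """A call violated a documented precondition."""


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physiological boundary conditions.

    p_la : constant left-atrial filling pressure (mmHg)
    p_cap : constant systemic capillary pressure (mmHg)
    t_cycle : cardiac cycle length (s)
    """

    p_la: float = 5.0
    p_cap: float = 20.0
    t_cycle: float = 0.11

    def __post_init__(self) -> None:
        if not (self.p_la > 0 and self.p_cap > 0 and self.t_cycle > 0):
            raise ContractError("ModelConstants fields must be strictly positive")


@dataclass
class ModelParameters:
    """The nine inferable circuit parameters.

    Resistances mmHg·s/µL, elastances mmHg/µL, times s, dead volume µL,
    compliance µL/mmHg.  ``t_s``/``t_e`` are the times of maximum and
    minimum elastance within the cycle.
    """

    r_mv: float = 5.0e-3
    r_av: float = 1.0e-3
    r_art: float = 2.68e-1
    e_es: float = 4.85
    e_ed: float = 1.46e-1
    t_s: float = 4.40e-2
    t_e: float = 7.70e-2
    v_lv_d: float = 5.0
    c_ao: float = 9.68e-1

    def validate(self, constants: ModelConstants | None = None) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ContractError("all model parameters must be finite and > 0")
        if not self.e_es > self.e_ed:
            raise ContractError("e_es must exceed e_ed")
        if not self.t_s < self.t_e:
            raise ContractError("t_s must precede t_e")
        if constants is not None and not self.t_e < constants.t_cycle:
            raise ContractError("t_e must precede the cycle length")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ContractError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def replace(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


#: A priori parameter ranges (lower, upper) used as optimization bounds and
#: uniform prior supports.  Timing ranges are fractions of the cycle length
#: scaled to seconds for the default 0.11 s cycle.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r_mv": (1.0e-4, 1.0e-2),
    "r_art": (0.1, 1.0),
    "e_es": (0.5, 6.0),
    "e_ed": (1.0e-2, 1.0),
    "t_s": (0.33 * 0.11, 0.66 * 0.11),
    "t_e": (0.66 * 0.11, 0.88 * 0.11),
    "v_lv_d": (1.0, 10.0),
    "c_ao": (0.4, 1.5),
}

#: The two parameters the reference analysis fixes at their a priori values.
DEFAULT_FIXED = ("r_av", "v_lv_d")
#: The seven-parameter free subset used throughout the worked analysis.
DEFAULT_FREE = tuple(n for n in PARAM_NAMES if n not in DEFAULT_FIXED)


@dataclass
class BeatSeries:
    """One converged periodic beat sampled on a uniform grid.

    Flows are the mitral (``q_mv``), aortic (``q_av``) and systemic
    (``q_sys``) branch flows in µL/s.  ``convergence_metric`` is the
    sup-norm relative change of the state trajectories between the last
    two simulated beats.
    """

    time: np.ndarray
    p_lv: np.ndarray
    p_ao: np.ndarray
    v_lv: np.ndarray
    q_mv: np.ndarray
    q_av: np.ndarray
    q_sys: np.ndarray
    n_beats_to_converge: int
    convergence_metric: float
    converged: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "P_LV": self.p_lv,
                "V_LV": self.v_lv,
                "P_Ao": self.p_ao,
                "Q_mv": self.q_mv,
                "Q_av": self.q_av,
                "Q_sys": self.q_sys,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elemental relations


@njit(cache=True)
def _elastance_scalar(t, e_es, e_ed, t_s, t_e, t_cycle):
    tt = t % t_cycle
    if tt < t_s:
        return e_ed + 0.5 * (e_es - e_ed) * (1.0 - math.cos(math.pi * tt / t_s))
    if tt < t_e:
        width = t_e - t_s
        if width <= 0.0:
            return e_ed
        return e_ed + 0.5 * (e_es - e_ed) * (1.0 + math.cos(math.pi * (tt - t_s) / width))
    return e_ed


def elastance(t, params: ModelParameters, constants: ModelConstants):
    """Time-varying LV elastance E(t) in mmHg/µL.

    Two-piece cosine ramp: rises from the diastolic floor ``e_ed`` to the
    end-systolic peak ``e_es`` over [0, t_s], relaxes back over [t_s, t_e],
    and stays at ``e_ed`` for the remainder of the cycle.  Periodic with
    period ``t_cycle``; continuous everywhere.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ContractError("elastance: time must be finite")
    tt = np.mod(t, constants.t_cycle)
    e_es, e_ed, t_s, t_e = params.e_es, params.e_ed, params.t_s, params.t_e
    amp = 0.5 * (e_es - e_ed)
    rise = e_ed + amp * (1.0 - np.cos(np.pi * tt / t_s))
    fall = e_ed + amp * (1.0 + np.cos(np.pi * (tt - t_s) / max(t_e - t_s, 1e-300)))
    out = np.where(tt < t_s, rise, np.where(tt < t_e, fall, e_ed))
    return float(out) if out.ndim == 0 else out


def lv_pressure(v_lv, t, params: ModelParameters, constants: ModelConstants):
    """Linear-elastance LV pressure P_lv = E(t)·(V_lv − V_lv,d) (mmHg).

    Negative values (V below the dead volume) are allowed and simply
    signal an unphysiological excursion.
    """
    return elastance(t, params, constants) * (np.asarray(v_lv, dtype=float) - params.v_lv_d)


def valve_flow(p_upstream, p_downstream, r):
    """Diode valve flow max((ΔP)/R, 0) in µL/s; never negative."""
    if np.any(np.asarray(r) <= 0):
        raise ContractError("valve resistance must be strictly positive")
    return np.maximum((np.asarray(p_upstream, dtype=float) - p_downstream) / r, 0.0)


def rhs(t, state, params: ModelParameters, constants: ModelConstants):
    """Right-hand side of the two-state circuit ODE.

    dV_lv/dt = Q_mv − Q_av,   dP_ao/dt = (Q_av − Q_sys)/C_ao,
    with Q_mv, Q_av diode flows and Q_sys = (P_ao − P_cap)/R_art
    (which may be negative while the aorta recharges).
    """
    v_lv, p_ao = float(state[0]), float(state[1])
    p_lv = float(lv_pressure(v_lv, t, params, constants))
    q_mv = float(valve_flow(constants.p_la, p_lv, params.r_mv))
    q_av = float(valve_flow(p_lv, p_ao, params.r_av))
    q_sys = (p_ao - constants.p_cap) / params.r_art
    return np.array([q_mv - q_av, (q_av - q_sys) / params.c_ao])


# ---------------------------------------------------------------------------
# periodic-beat integration (jitted fixed-step RK4 with stiffness-aware step)


@njit(cache=True)
def _rhs_jit(t, v_lv, p_ao, r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao, p_la, p_cap, t_cycle):
    e = _elastance_scalar(t, e_es, e_ed, t_s, t_e, t_cycle)
    p_lv = e * (v_lv - v_lv_d)
    q_mv = (p_la - p_lv) / r_mv
    if q_mv < 0.0:
        q_mv = 0.0
    q_av = (p_lv - p_ao) / r_av
    if q_av < 0.0:
        q_av = 0.0
    q_sys = (p_ao - p_cap) / r_art
    return q_mv - q_av, (q_av - q_sys) / c_ao


@njit(cache=True)
def _integrate(theta, p_la, p_cap, t_cycle, n_sample, n_sub, v0, p0, max_beats, tol):
    """Beat-by-beat RK4 integration until the sampled (V_lv, P_ao)
    trajectories of consecutive beats agree to ``tol`` in sup norm
    (relative to each signal's amplitude)."""
    r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao = theta
    dt = t_cycle / (n_sample * n_sub)
    v_cur = np.empty(n_sample)
    p_cur = np.empty(n_sample)
    v_prev = np.empty(n_sample)
    p_prev = np.empty(n_sample)
    v, p = v0, p0
    metric = np.inf
    n_beats = 0
    for beat in range(max_beats):
        for k in range(n_sample):
            v_cur[k] = v
            p_cur[k] = p
            t0 = k * n_sub * dt
            for j in range(n_sub):
                t = t0 + j * dt
                k1v, k1p = _rhs_jit(t, v, p, r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao, p_la, p_cap, t_cycle)
                k2v, k2p = _rhs_jit(t + 0.5 * dt, v + 0.5 * dt * k1v, p + 0.5 * dt * k1p, r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao, p_la, p_cap, t_cycle)
                k3v, k3p = _rhs_jit(t + 0.5 * dt, v + 0.5 * dt * k2v, p + 0.5 * dt * k2p, r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao, p_la, p_cap, t_cycle)
                k4v, k4p = _rhs_jit(t + dt, v + dt * k3v, p + dt * k3p, r_mv, r_av, r_art, e_es, e_ed, t_s, t_e, v_lv_d, c_ao, p_la, p_cap, t_cycle)
                v = v + dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
                p = p + dt * (k1p + 2.0 * k2p + 2.0 * k3p + k4p) / 6.0
            if not (math.isfinite(v) and math.isfinite(p)):
                return v_cur, p_cur, beat + 1, np.nan, -1
        n_beats = beat + 1
        if beat > 0:
            dv = 0.0
            dp = 0.0
            va = 0.0
            pa = 0.0
            for k in range(n_sample):
                dv = max(dv, abs(v_cur[k] - v_prev[k]))
                dp = max(dp, abs(p_cur[k] - p_prev[k]))
                va = max(va, abs(v_cur[k]))
                pa = max(pa, abs(p_cur[k]))
            metric = max(dv / max(va, 1e-300), dp / max(pa, 1e-300))
            if metric < tol:
                return v_cur, p_cur, n_beats, metric, 1
        v_prev[:] = v_cur
        p_prev[:] = p_cur
    return v_cur, p_cur, n_beats, metric, 0


def _n_substeps(params: ModelParameters, constants: ModelConstants, n_sample: int) -> int:
    # Fastest linear relaxation times of the circuit: LV drained through
    # either valve at peak elastance, and the aortic RC loop through the
    # open aortic valve.  Fixed RK4 needs dt well inside these.
    tau = min(
        params.r_mv / params.e_es,
        params.r_av / params.e_es,
        params.r_av * params.c_ao,
        params.r_art * params.c_ao,
    )
    dt_max = 0.25 * tau
    sample_dt = constants.t_cycle / n_sample
    return max(int(np.ceil(sample_dt / dt_max)), 10)


def simulate_to_steady_beat(
    params: ModelParameters,
    constants: ModelConstants | None = None,
    dt: float | None = None,
    max_beats: int = 50,
    tol: float = 1.0e-6,
    sampling_rate: float = 500.0,
    initial_state: tuple[float, float] = (40.0, 70.0),
) -> BeatSeries:
    """Integrate beat-by-beat to the periodic steady state.

    The converged beat is returned sampled at ``sampling_rate`` on the
    endpoint-excluded grid t_k = k / f_s.  If ``dt`` is given it is used as
    the (approximate) internal step; otherwise a stiffness-aware step is
    chosen from the circuit time constants.  Non-convergence within
    ``max_beats`` yields a warning and ``converged=False``; a non-finite
    state aborts with an error naming the parameter set.
    """
    constants = constants or ModelConstants()
    if tol <= 0:
        raise ContractError("tol must be positive")
    params.validate(constants)
    n_sample = int(round(sampling_rate * constants.t_cycle))
    if dt is None:
        n_sub = _n_substeps(params, constants, n_sample)
    else:
        n_sub = max(int(round(constants.t_cycle / (n_sample * dt))), 1)
    v, p, n_beats, metric, status = _integrate(
        params.to_array(),
        constants.p_la,
        constants.p_cap,
        constants.t_cycle,
        n_sample,
        n_sub,
        float(initial_state[0]),
        float(initial_state[1]),
        int(max_beats),
        float(tol),
    )
    if status < 0:
        raise FloatingPointError(
            f"simulation produced a non-finite state for parameters {params!r}"
        )
    if status == 0:
        warnings.warn(
            f"beat did not reach periodicity within {max_beats} beats "
            f"(metric {metric:.3g} > tol {tol:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    time = np.arange(n_sample) / sampling_rate
    p_lv = np.asarray(lv_pressure(v, time, params, constants), dtype=float)
    q_mv = valve_flow(constants.p_la, p_lv, params.r_mv)
    q_av = valve_flow(p_lv, p, params.r_av)
    q_sys = (p - constants.p_cap) / params.r_art
    return BeatSeries(
        time=time,
        p_lv=p_lv,
        p_ao=np.asarray(p, dtype=float),
        v_lv=np.asarray(v, dtype=float),
        q_mv=q_mv,
        q_av=q_av,
        q_sys=q_sys,
        n_beats_to_converge=int(n_beats),
        convergence_metric=float(metric),
        converged=status == 1,
    )


def stacked_output(
    params: ModelParameters,
    constants: ModelConstants | None = None,
    sampling_rate: float = 500.0,
) -> np.ndarray:
    """Converged-beat model output stacked as (V_lv, P_lv, P_ao)."""
    beat = simulate_to_steady_beat(params, constants, sampling_rate=sampling_rate)
    return np.concatenate([beat.v_lv, beat.p_lv, beat.p_ao])


def beat_summary(beat: BeatSeries) -> dict[str, float]:
    """Scalar summaries of a beat (systolic/diastolic extrema, stroke
    volume, mean aortic pressure, cardiac output)."""
    if beat.time.size == 0:
        raise ContractError("beat_summary: empty beat")
    t_cycle = beat.time.size * (beat.time[1] - beat.time[0]) if beat.time.size > 1 else np.nan
    sv = float(np.max(beat.v_lv) - np.min(beat.v_lv))
    return {
        "max_p_lv": float(np.max(beat.p_lv)),
        "min_p_lv": float(np.min(beat.p_lv)),
        "max_v_lv": float(np.max(beat.v_lv)),
        "min_v_lv": float(np.min(beat.v_lv)),
        "max_p_ao": float(np.max(beat.p_ao)),
        "min_p_ao": float(np.min(beat.p_ao)),
        "mean_p_ao": float(np.mean(beat.p_ao)),
        "stroke_volume": sv,
        "cardiac_output": sv / t_cycle,
    }
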