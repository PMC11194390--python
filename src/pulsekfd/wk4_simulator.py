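"""Four-element Windkessel (WK4) simulators with fixed or time-varying C1.

Two zero-dimensional lumped circulation models are provided.  Both share
the topology: a half-sine ejection inflow ``q_in(t)`` charges a central
compliance C1; an inertance L and the peripheral compliance C2 / resistance
R form the peripheral node whose pressure ``p_p(t)`` is the PPG surrogate.

Fixed-C1 model (first-order system)::

    dq/dt   = (p_c - p_p) / L
    dp_c/dt = (q_in - q) / C1
    dp_p/dt = (q - p_p / R) / C2

Time-varying-C1 model: the same system with C1 replaced by a strictly
positive, cycle-periodic C1(t).  Eliminating q and p_c yields a third-order
ODE in ``p_p`` alone; integrating the first-order system with C1 -> C1(t)
is mathematically equivalent and is what this module does.

The default C1(t) law models pressure-dependent stiffening: compliance
falls as the vessel distends,

    C1(t) = C1_baseline * (1 - m * s(t)),

where ``s(t)`` is the central pressure of the previous warm-up cycle
rescaled to [0, 1] (a distension proxy) and ``m`` is a single dimensionless
modulation depth (default 0.3, valid range [0, 0.5]).  The law is pluggable
via the ``c1_law`` argument of :func:`simulate_varying_c1`.

Simulations run cycle by cycle from a mean-pressure initial state until the
peripheral pressure repeats to within ``tol`` mmHg (periodic steady state),
then return the final cycle resampled to ``fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from pulsekfd.errors import ConvergenceError, DataError, ParameterError
from pulsekfd.preprocess import PulseBeat

DEFAULT_FS = 500.0
DEFAULT_L_INERTANCE = 0.02  # mmHg s^2 / mL, typical WK4 magnitude
DEFAULT_C2_RATIO = 0.08  # C2 = ratio * C1_baseline
DEFAULT_T_SYSTOLE_FRACTION = 0.35
DEFAULT_C1_MODULATION = 0.3
CONVERGENCE_TOL_MMHG = 0.1
MAX_WARMUP_CYCLES = 50

__all__ = [
    "HemodynamicProfile",
    "InflowWave",
    "Wk4Solution",
    "make_inflow",
    "simulate_fixed_c1",
    "simulate_varying_c1",
    "volume_beat_from_solution",
    "default_c1_law",
]


@dataclass(frozen=True)
class HemodynamicProfile:
    """One virtual subject's lumped-model parameter set.

    Units: compliances mL/mmHg, resistance mmHg·s/mL, inertance
    mmHg·s²/mL, stroke volume mL, heart rate Hz.
    """

    C1_baseline: float
    C2: float
    R: float
    SV: float
    HR: float
    L_inertance: float = DEFAULT_L_INERTANCE
    C1_modulation: float = 0.0
    T_systole_fraction: float = DEFAULT_T_SYSTOLE_FRACTION

    def __post_init__(self):
        for name in ("C1_baseline", "C2", "R", "SV", "HR", "L_inertance"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive and finite")
        if not 0.0 < self.T_systole_fraction < 1.0:
            raise ParameterError("T_systole_fraction must be in (0, 1)")
        if not 0.0 <= self.C1_modulation < 1.0:
            raise ParameterError(
                "C1_modulation must be in [0, 1) to keep C1(t) positive"
            )

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 1.0 / self.HR

    def with_modulation(self, m: float) -> "HemodynamicProfile":
        return replace(self, C1_modulation=m)


@dataclass
class InflowWave:
    """One cycle of cardiac inflow q_in(t), mL/s, uniformly sampled."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.samples.ndim != 1 or self.samples.size < 4:
            raise ParameterError("inflow must be a 1-D series of >= 4 samples")
        if np.any(self.samples < -1e-12):
            raise ParameterError("inflow must be nonnegative")

    @property
    def period(self) -> float:
        return self.samples.size / self.fs

    @property
    def stroke_volume(self) -> float:
        """Integral over one (periodic) cycle, mL."""
        closed = np.append(self.samples, self.samples[0])
        return float(np.trapezoid(closed, dx=1.0 / self.fs))


@dataclass
class Wk4Solution:
    """Periodic steady-state waveforms over one cardiac cycle."""

    p_c: np.ndarray  # central pressure, mmHg
    p_p: np.ndarray  # peripheral pressure, mmHg
    q: np.ndarray  # vascular flow, mL/s
    fs: float
    HR: float
    converged: bool
    n_warmup_cycles: int
    residual: float  # last cycle-to-cycle max |delta p_p|, mmHg
    mean_c1: float  # time-average of C1(t); == C1_baseline for fixed model

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.p_p.size) / self.fs

    @property
    def pulse_pressure(self) -> float:
        """Peripheral pulse pressure max(p_p) - min(p_p), mmHg."""
        return float(np.max(self.p_p) - np.min(self.p_p))


def make_inflow(
    SV: float,
    HR: float,
    T_systole_fraction: float = DEFAULT_T_SYSTOLE_FRACTION,
    fs: float = DEFAULT_FS,
) -> InflowWave:
    """Half-sine systolic ejection pulse integrating to SV over the cycle.

    The pulse spans [0, T_systole_fraction / HR] and is zero in diastole;
    samples are rescaled so the trapezoidal integral over the periodic
    cycle equals SV exactly.
    """
    if SV <= 0 or HR <= 0 or fs <= 0 or T_systole_fraction <= 0:
        raise ParameterError("all inflow parameters must be positive")
    if T_systole_fraction >= 1:
        raise ParameterError("T_systole_fraction must be < 1")
    if fs < 100:
        raise ParameterError("fs must be >= 100 Hz to resolve the ejection pulse")
    T = 1.0 / HR
    n = int(round(fs * T))
    if n < 8:
        raise ParameterError("cycle too short at this sampling rate")
    t = np.arange(n) / fs
    T_sys = T_systole_fraction * T
    peak = SV * np.pi * HR / (2.0 * T_systole_fraction)
    q = np.where(t < T_sys, peak * np.sin(np.pi * np.minimum(t, T_sys) / T_sys), 0.0)
    wave = InflowWave(samples=q, fs=fs)
    wave.samples = wave.samples * (SV / wave.stroke_volume)
    return wave


def default_c1_law(profile: HemodynamicProfile, s: np.ndarray) -> np.ndarray:
    """Pressure-dependent stiffening: C1(t) = C1_baseline (1 - m s(t))."""
    c1 = profile.C1_baseline * (1.0 - profile.C1_modulation * s)
    if np.any(c1 <= 0):
        raise ParameterError("C1(t) must stay positive; reduce C1_modulation")
    return c1


def _normalize_distension(p_c_cycle: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(p_c_cycle)), float(np.max(p_c_cycle))
    if hi - lo <= 0:
        return np.zeros_like(p_c_cycle)
    return (p_c_cycle - lo) / (hi - lo)


def _periodic_spline(samples: np.ndarray, period: float) -> CubicSpline:
    n = samples.size
    t = np.arange(n + 1) * (period / n)
    y = np.append(samples, samples[0])
    return CubicSpline(t, y, bc_type="periodic")


def _simulate(
    profile: HemodynamicProfile,
    inflow: InflowWave,
    fs: float,
    varying: bool,
    c1_law: Callable[[HemodynamicProfile, np.ndarray], np.ndarray],
    tol: float,
    max_cycles: int,
    rtol: float,
    atol: float,
) -> Wk4Solution:
    T = profile.period
    if abs(inflow.period - T) > 0.5 / inflow.fs + 1e-9:
        raise ParameterError(
            f"inflow period {inflow.period:.4f} s does not match 1/HR = {T:.4f} s"
        )
    qin = _periodic_spline(inflow.samples, T)

    n_out = int(round(fs * T))
    t_out = np.arange(n_out) / fs

    R, C2, L = profile.R, profile.C2, profile.L_inertance
    mean_p = profile.SV * profile.HR * R
    y = np.array([profile.SV * profile.HR, mean_p, mean_p])  # [q, p_c, p_p]

    # distension proxy from the previous cycle, on the output grid
    s_grid = np.zeros(n_out)
    prev_pp = None
    residual = np.inf
    converged = False
    n_cycles = 0
    p_c_out = p_p_out = q_out = None

    for cycle in range(max_cycles):
        n_cycles = cycle + 1
        if varying:
            c1_grid = c1_law(profile, s_grid)
            c1_spline = _periodic_spline(c1_grid, T)

            def rhs(t, y):
                q_, pc, pp = y
                tm = t % T
                c1 = c1_spline(tm)
                return (
                    (pc - pp) / L,
                    (qin(tm) - q_) / c1,
                    (q_ - pp / R) / C2,
                )

        else:
            C1 = profile.C1_baseline

            def rhs(t, y):
                q_, pc, pp = y
                tm = t % T
                return (
                    (pc - pp) / L,
                    (qin(tm) - q_) / C1,
                    (q_ - pp / R) / C2,
                )

        sol = solve_ivp(
            rhs,
            (0.0, T),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
            max_step=T / 50.0,
        )
        if not sol.success:
            raise ConvergenceError(f"integrator failed: {sol.message}")
        y = sol.y[:, -1]
        cycle_vals = sol.sol(t_out)
        q_out, p_c_out, p_p_out = cycle_vals[0], cycle_vals[1], cycle_vals[2]
        if varying:
            s_grid = _normalize_distension(p_c_out)
        if prev_pp is not None:
            residual = float(np.max(np.abs(p_p_out - prev_pp)))
            if residual < tol:
                converged = True
                break
        prev_pp = p_p_out.copy()

    if not converged:
        raise ConvergenceError(
            f"no periodic steady state after {max_cycles} cycles "
            f"(last residual {residual:.3g} mmHg)",
            residual=residual,
        )

    if varying:
        mean_c1 = float(np.mean(c1_law(profile, s_grid)))
    else:
        mean_c1 = profile.C1_baseline

    return Wk4Solution(
        p_c=p_c_out,
        p_p=p_p_out,
        q=q_out,
        fs=fs,
        HR=profile.HR,
        converged=converged,
        n_warmup_cycles=n_cycles,
        residual=residual,
        mean_c1=mean_c1,
    )


def simulate_fixed_c1(
    profile: HemodynamicProfile,
    inflow: InflowWave,
    fs: float = DEFAULT_FS,
    tol: float = CONVERGENCE_TOL_MMHG,
    max_cycles: int = MAX_WARMUP_CYCLES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Wk4Solution:
    """Integrate the fixed-C1 WK4 model to periodic steady state.

    Returns the final cycle sampled at ``fs``.  Raises
    :class:`ConvergenceError` if the cycle-to-cycle peripheral-pressure
    residual stays above ``tol`` mmHg for ``max_cycles`` warm-up cycles.
    """
    return _simulate(
        profile, inflow, fs, False, default_c1_law, tol, max_cycles, rtol, atol
    )


def simulate_varying_c1(
    profile: HemodynamicProfile,
    inflow: InflowWave,
    fs: float = DEFAULT_FS,
    c1_law: Callable[[HemodynamicProfile, np.ndarray], np.ndarray] = default_c1_law,
    tol: float = CONVERGENCE_TOL_MMHG,
    max_cycles: int = MAX_WARMUP_CYCLES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Wk4Solution:
    """Integrate the WK4 model with cycle-periodic time-varying C1(t).

    ``c1_law(profile, s)`` maps the normalized distension proxy ``s``
    (previous cycle's central pressure rescaled to [0, 1]) to C1(t) > 0.
    With ``C1_modulation == 0`` the model reduces to the fixed-C1 system.
    """
    return _simulate(
        profile, inflow, fs, True, c1_law, tol, max_cycles, rtol, atol
    )


def volume_beat_from_solution(sol: Wk4Solution, C2: float) -> PulseBeat:
    """Map a converged WK4 cycle to a PPG-surrogate volume beat.

    The peripheral pulsatile volume is taken as V(t) = C2 * p_p(t), so the
    per-beat pulsatile amplitude is delta_v = C2 * (max p_p - min p_p) in mL.
    """
    if not np.all(np.isfinite(sol.p_p)):
        raise DataError("non-finite pressures in solution")
    if C2 <= 0:
        raise ParameterError("C2 must be positive")
    if not sol.converged:
        raise DataError("solution did not converge; refusing to extract a beat")
    v = C2 * sol.p_p
    delta_v = float(C2 * (np.max(sol.p_p) - np.min(sol.p_p)))
    return PulseBeat(samples=v, fs=sol.fs, HR=sol.HR, delta_v=delta_v)
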