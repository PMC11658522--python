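"""Laser-driver design formulas and the two-stage transimpedance amplifier.

Driver side (automatic power control IC): the average monitor current of
the laser's built-in photodiode is programmed with a set resistor,

    R_SET + R_SET2 = CR * V(ISET) / I_av(AMD),

where pulsed operation at duty d makes I_av = I_monitor * d, and the
integrator capacitor must satisfy C_I >= 440 / (f * (R_SET + R_SET2)) at
pulse repetition frequency f.

Amplifier side: stage 1 is a transimpedance stage (gain G1 = R_F1, single
pole at 1/(2 pi R_F1 C_F1)), AC-coupled through C_6 into R_4 (high-pass
time constant tau = R_4 C_6), and stage 2 is an inverting amplifier
(G2 = R_F2 / R_4, pole at 1/(2 pi R_F2 C_F2)).  Both op-amps run from a
single 5 V supply with the non-inverting inputs biased at 2.7 V, so every
node voltage is confined to [0, V_supply] and the quiescent output sits at
the bias.

Two sign conventions coexist in the device's own design arithmetic and
both are provided:

* :func:`steady_state_output` is DC-referenced: a photocurrent step of
  amplitude I swings the second stage *downward* from bias by I*G1*G2
  ("amplifies the signal towards ground"); this is the convention behind
  the 1.32 V bench figure and the 831 kV/A saturation gain.
* :func:`transient_response` / :func:`square_wave_levels` follow the
  AC-coupled path: the coupling capacitor removes the duty-weighted mean,
  so a two-level square-wave input emerges symmetric about the bias
  (3.693 V / 1.707 V for the 432/101 nA pair at G1*G2 = 6 MV/A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InfeasibleDesignError",
    "DriverDesign",
    "TIAParams",
    "TransientTrace",
    "rset_for_monitor",
    "min_integrator_cap",
    "corner_frequency",
    "stage_bandwidth",
    "steady_state_output",
    "square_wave_levels",
    "saturation_gain",
    "transient_response",
    "frequency_response",
    "minus_3db_frequency",
]

ELEMENTARY_CHARGE = 1.602176634e-19


class InfeasibleDesignError(ValueError):
    """A closed-form design equation produced an unrealizable component."""


@dataclass(frozen=True)
class DriverDesign:
    """Inputs of the APC driver design equations (SI units)."""

    i_monitor: float            # monitor-current amplitude, A
    duty: float = 0.5
    f_pulse: float = 55.0       # pulse repetition frequency, Hz
    cr: float = 1.0             # IC current ratio
    v_iset: float = 1.22        # IC reference voltage, V
    r_set2: float = 2.7e3       # fixed series resistor, Ohm

    def __post_init__(self) -> None:
        if not 0 < self.duty <= 1:
            raise ValueError("duty must lie in (0, 1]")
        if self.i_monitor <= 0:
            raise ValueError("i_monitor must be positive")
        if self.f_pulse <= 0:
            raise ValueError("f_pulse must be positive")


@dataclass(frozen=True)
class TIAParams:
    """Component values of the two-stage amplifier (SI units).

    Derived quantities: ``g1 = r_f1`` (V/A), ``g2 = r_f2 / r_4`` (V/V),
    ``tau = r_4 * c_6`` (s, the AC-coupling time constant).
    """

    r_f1: float = 600e3
    c_f1: float = 6.8e-12
    r_f2: float = 470e3
    c_f2: float = 6.8e-12
    r_4: float = 47e3
    r_2: float = 22e3
    r_3: float = 27e3
    c_s: float = 1e-6
    c_6: float = 10e-6
    v_bias: float = 2.7
    v_supply: float = 5.0

    def __post_init__(self) -> None:
        for name in ("r_f1", "c_f1", "r_f2", "c_f2", "r_4", "r_2", "r_3",
                     "c_s", "c_6"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.v_bias <= self.v_supply:
            raise ValueError("require 0 <= v_bias <= v_supply")

    @property
    def g1(self) -> float:
        return self.r_f1

    @property
    def g2(self) -> float:
        return self.r_f2 / self.r_4

    @property
    def g_total(self) -> float:
        return self.g1 * self.g2

    @property
    def tau(self) -> float:
        return self.r_4 * self.c_6

    @property
    def f_stage1(self) -> float:
        return stage_bandwidth(self.r_f1, self.c_f1)

    @property
    def f_stage2(self) -> float:
        return stage_bandwidth(self.r_f2, self.c_f2)

    @property
    def f_highpass(self) -> float:
        return 1.0 / (2.0 * math.pi * self.tau)

    @property
    def f_bias_corner(self) -> float:
        return corner_frequency(self.r_2, self.r_3, self.c_s)

    def clip(self, v):
        return np.clip(v, 0.0, self.v_supply)


def rset_for_monitor(design: DriverDesign) -> float:
    """Set resistor R_SET (Ohm) programming the average monitor current.

    Raises :class:`InfeasibleDesignError` when the requested average
    current already exceeds what the fixed series resistor alone allows
    (negative R_SET).
    """
    i_av = design.i_monitor * design.duty
    r_set = design.cr * design.v_iset / i_av - design.r_set2
    if r_set < 0:
        raise InfeasibleDesignError(
            f"average monitor current {i_av:.3g} A needs total resistance "
            f"below the fixed R_SET2 = {design.r_set2:.3g} Ohm")
    return r_set


def min_integrator_cap(f_pulse: float, r_total: float) -> float:
    """Minimum integrator capacitance C_I (F) for pulsed operation at
    repetition frequency *f_pulse* with total set resistance *r_total*."""
    if f_pulse <= 0 or r_total <= 0:
        raise ValueError("f_pulse and r_total must be positive")
    return 440.0 / (f_pulse * r_total)


def corner_frequency(r_2: float, r_3: float, c_s: float) -> float:
    """-3 dB corner (Hz) of the bias divider's noise filter: C_S across the
    parallel combination of the divider resistors."""
    if min(r_2, r_3, c_s) <= 0:
        raise ValueError("components must be positive")
    r_par = r_2 * r_3 / (r_2 + r_3)
    return 1.0 / (2.0 * math.pi * r_par * c_s)


def stage_bandwidth(r_f: float, c_f: float) -> float:
    """-3 dB bandwidth (Hz) of one amplifier stage's feedback network."""
    if r_f <= 0 or c_f <= 0:
        raise ValueError("components must be positive")
    return 1.0 / (2.0 * math.pi * r_f * c_f)


def steady_state_output(i_pd: float, params: TIAParams = TIAParams()):
    """DC-referenced stage outputs (V) for a constant photocurrent.

    Stage 1 rises from the bias by ``i_pd * G1``; the inverting second
    stage swings the output from the bias toward ground by
    ``i_pd * G1 * G2``.  Both outputs clip to [0, V_supply].  At zero input
    both stages idle at the bias (the AC coupling passes no DC, so a truly
    steady current also decays there — this function reports the
    pre-decay plateau the design formulas reason about).
    """
    if i_pd < 0:
        raise ValueError("i_pd must be >= 0")
    v1 = params.clip(params.v_bias + i_pd * params.g1)
    v2 = params.clip(params.v_bias - i_pd * params.g_total)
    return float(v1), float(v2)


def saturation_gain(i_pd: float, params: TIAParams = TIAParams()) -> float:
    """First-stage gain (V/A) at which the second stage just reaches the
    0 V rail for photocurrent *i_pd* (onset of output saturation)."""
    if i_pd <= 0:
        raise ValueError("i_pd must be positive")
    return params.v_bias / (i_pd * params.g2)


def square_wave_levels(i_high: float, i_low: float,
                       params: TIAParams = TIAParams(), duty: float = 0.5):
    """Steady-state second-stage levels for a two-level AC-coupled input.

    The coupling capacitor removes the duty-weighted mean current, so the
    output splits about the bias: the high-current phase maps to
    ``v_bias - (i_high - i_mean) * G``, the low phase to
    ``v_bias + (i_mean - i_low) * G`` (inverting stage).  Returns
    ``(level_during_high, level_during_low)``, clipped to the rails.
    """
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    i_mean = duty * i_high + (1.0 - duty) * i_low
    g = params.g_total
    v_high = params.clip(params.v_bias - (i_high - i_mean) * g)
    v_low = params.clip(params.v_bias - (i_low - i_mean) * g)
    return float(v_high), float(v_low)


@dataclass(frozen=True)
class TransientTrace:
    """Time-domain response of the amplifier chain.

    ``v_cap`` is the voltage on the coupling capacitor C_6 (the slow state
    whose charging sets the power-on settling); ``drive_high`` marks the
    samples during which the input square wave sits at its high level.
    """

    t: np.ndarray
    v_stage1: np.ndarray
    v_stage2: np.ndarray
    v_cap: np.ndarray
    drive_high: np.ndarray
    params: TIAParams

    def steady_state_peak_to_peak(self, stage: int = 2,
                                  tail_fraction: float = 0.25,
                                  plateau_guard: float = 0.05) -> float:
        """Peak-to-peak swing measured as the difference between the
        settled plateau means of the high and low input phases over the
        final *tail_fraction* of the trace.

        *plateau_guard* discards the leading fraction of every half-cycle
        so edge transients of the stage low-pass poles do not bias the
        plateau means.
        """
        v = self.v_stage1 if stage == 1 else self.v_stage2
        n0 = int(len(v) * (1.0 - tail_fraction))
        # index within the current half-cycle, to apply the guard
        phase = self.drive_high.astype(np.int8)
        edges = np.flatnonzero(np.diff(phase) != 0) + 1
        pos = np.arange(len(v))
        start = np.zeros(len(v), dtype=np.int64)
        start[edges] = edges
        start = np.maximum.accumulate(start)
        nxt = np.full(len(v), len(v), dtype=np.int64)
        nxt[edges - 1] = edges
        nxt = np.minimum.accumulate(nxt[::-1])[::-1]
        frac = (pos - start) / np.maximum(nxt - start, 1)
        ok = (pos >= n0) & (frac >= plateau_guard)
        hi = v[ok & self.drive_high]
        lo = v[ok & ~self.drive_high]
        if len(hi) == 0 or len(lo) == 0:
            raise ValueError("trace too short to isolate settled plateaus")
        return float(abs(hi.mean() - lo.mean()))

    def settling_time(self, tol: float = 0.02) -> float:
        """Time (s) for the coupling capacitor to charge to within *tol*
        of its equilibrium voltage (tol = 0.02 corresponds to ~4 tau)."""
        vc = self.v_cap
        v_final = vc[-1]
        dv0 = abs(v_final - vc[0])
        if dv0 == 0:
            return 0.0
        settled = np.abs(vc - v_final) <= tol * dv0
        # first index after which it stays settled
        idx = len(vc) - 1
        for i in range(len(vc) - 1, -1, -1):
            if not settled[i]:
                break
            idx = i
        return float(self.t[idx])

    def cycle_mean(self, stage: int = 2, at: float | None = None) -> float:
        """Mean of one full input cycle of the stage output, centred near
        time *at* (defaults to the end of the trace)."""
        v = self.v_stage1 if stage == 1 else self.v_stage2
        edges = np.flatnonzero(np.diff(self.drive_high.astype(np.int8)) > 0) + 1
        if len(edges) < 2:
            return float(v.mean())
        i = len(edges) - 2 if at is None else int(
            np.clip(np.searchsorted(self.t[edges], at) - 1, 0, len(edges) - 2))
        return float(v[edges[i]:edges[i + 1]].mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.t, "stage1_v": self.v_stage1,
                             "stage2_v": self.v_stage2})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _one_pole_lowpass(x: np.ndarray, dt: float, f_pole: float,
                      y0: float) -> np.ndarray:
    """Exact zero-order-hold discretization of a single-pole low-pass."""
    from scipy.signal import lfilter, lfiltic

    a = math.exp(-2.0 * math.pi * f_pole * dt)
    b = [1.0 - a]
    aa = [1.0, -a]
    zi = lfiltic(b, aa, y=[y0])
    y, _ = lfilter(b, aa, x, zi=zi)
    return y


def transient_response(i_high: float, i_low: float, frequency: float,
                       params: TIAParams = TIAParams(),
                       duration: float = 2.0, duty: float = 0.5,
                       samples_per_cycle: int = 200,
                       power_on: bool = True) -> TransientTrace:
    """Simulate the chain for a square-wave photocurrent drive.

    The input alternates between *i_high* and *i_low* at *frequency* with
    the given *duty*.  Stage 1 responds through its feedback pole, the
    C_6/R_4 network high-passes the result (exact piecewise-exponential
    update of the capacitor state; tau = R_4*C_6), and the inverting second
    stage applies G2 through its own pole.  All node voltages clip to
    [0, V_supply].

    With ``power_on=True`` the coupling capacitor starts discharged, which
    reproduces the device's initialization phase: the output sits at a rail
    and creeps to the bias voltage over ~4 tau (about two seconds for the
    default 0.47 s time constant).  ``power_on=False`` starts settled.
    """
    if duration <= 0 or frequency <= 0:
        raise ValueError("duration and frequency must be positive")
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    spc = int(samples_per_cycle)
    dt = 1.0 / (frequency * spc)
    n = max(int(round(duration / dt)), 2 * spc)
    k = np.arange(n)
    drive_high = (k % spc) < duty * spc
    i_in = np.where(drive_high, i_high, i_low)

    # stage 1: DC-referenced TIA output through its feedback pole
    x1 = params.v_bias + i_in * params.g1
    v1 = params.clip(_one_pole_lowpass(x1, dt, params.f_stage1, x1[0]))

    # AC coupling: exact exponential charge of C_6 toward the stage-1 node
    alpha = 1.0 - math.exp(-dt / params.tau)
    vc = np.empty(n)
    state = 0.0 if power_on else float(
        duty * (params.v_bias + i_high * params.g1)
        + (1 - duty) * (params.v_bias + i_low * params.g1))
    for i in range(n):
        state += (v1[i] - state) * alpha
        vc[i] = state
    y_hp = v1 - vc

    # stage 2: inverting gain through its pole, clipped to the rails
    x2 = params.v_bias - params.g2 * y_hp
    v2 = params.clip(_one_pole_lowpass(x2, dt, params.f_stage2, x2[0]))

    return TransientTrace(t=k * dt, v_stage1=v1, v_stage2=v2, v_cap=vc,
                          drive_high=drive_high, params=params)


def frequency_response(params: TIAParams, f) -> np.ndarray:
    """Magnitude of the small-signal transimpedance |H(f)| in V/A.

    Passband gain G1*G2 rolled off by the two stage poles and high-passed
    by the C_6/R_4 coupling corner.  Note that with the default components
    the two poles (39 kHz and 50 kHz) are comparable, so the combined
    -3 dB point sits below either single-stage figure; the single-stage
    design numbers come from :func:`stage_bandwidth`.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    hp = (f / params.f_highpass) / np.sqrt(1.0 + (f / params.f_highpass) ** 2)
    lp1 = 1.0 / np.sqrt(1.0 + (f / params.f_stage1) ** 2)
    lp2 = 1.0 / np.sqrt(1.0 + (f / params.f_stage2) ** 2)
    return params.g_total * hp * lp1 * lp2


def minus_3db_frequency(params: TIAParams, f_lo: float = 10.0,
                        f_hi: float = 1e7) -> float:
    """Upper -3 dB frequency of :func:`frequency_response`, located
    numerically by bisection against the passband gain."""
    from scipy.optimize import brentq

    g_ref = params.g_total / math.sqrt(2.0)

    def excess(logf):
        return float(frequency_response(params, [10.0 ** logf])[0]) - g_ref

    return 10.0 ** brentq(excess, math.log10(max(f_lo, 2 * params.f_highpass)),
                          math.log10(f_hi))
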