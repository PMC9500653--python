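"""Nociceptor mechanotransduction: stress in, firing frequency out.

The nociceptor membrane is a modified Hodgkin-Huxley model of the
Connor-Stevens type: fast sodium, delayed-rectifier potassium, a fast
transient potassium (A-type) current, and a leak, driven by a
mechanosensitive current that switches on when the local stress magnitude
exceeds a mechanical threshold ``sigma_t``:

    C_m dV/dt = I_mech(sigma) + I_shift - (I_Na + I_K + I_A + I_L)

    I_mech = [C_m1 exp((sigma - sigma_t) / (sigma_t C_m2)) + C_m3] H(sigma - sigma_t)

Five gating variables (m, h, n for Na/K; A, B for the A-current) relax
toward voltage-dependent steady states, tau_x dx/dt = x_inf - x.  The
suprarheobase bias ``I_shift`` is applied only while the stimulus is above
threshold, so the unstimulated membrane is quiescent.

Stimulus intensity is encoded in the firing *frequency* of the membrane
potential, extracted from the post-transient trace either by FFT (largest
non-DC spectral peak) or by counting upward zero crossings.

Time is in ms, potentials in mV, current densities in uA/cm^2,
conductances in mS/cm^2, stress in kPa; frequencies are reported in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HHParams",
    "MembraneState",
    "GatingKinetics",
    "MembraneTrace",
    "SpikeSummary",
    "mech_current",
    "gating_kinetics",
    "membrane_rhs",
    "resting_potential",
    "initial_state",
    "simulate_membrane",
    "firing_frequency",
    "firing_onset_stress",
]


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters of the modified Hodgkin-Huxley nociceptor model.

    Defaults are the Connor-Stevens parameterisation: maximal conductances
    120 / 20 / 47.7 mS/cm^2 for Na / K / A-current and reversal potentials
    55 / -72 / -75 mV, with a leak (0.3 mS/cm^2 toward -17.5 mV).  The
    mechanosensitive current uses threshold sigma_t = 20 kPa and constants
    C_m1 = 2 uA/cm^2, C_m2 = 2, C_m3 = -1 uA/cm^2; I_shift = 8.1 uA/cm^2
    is a bias applied above threshold to guarantee repetitive firing.
    """

    C_m: float = 1.0  # membrane capacitance, uF/cm^2
    kappa_Na: float = 120.0
    kappa_K: float = 20.0
    kappa_A: float = 47.7
    kappa_L: float = 0.3
    E_Na: float = 55.0
    E_K: float = -72.0
    E_A: float = -75.0
    E_L: float = -17.5
    C_m1: float = 2.0
    C_m2: float = 2.0
    C_m3: float = -1.0
    sigma_t: float = 20.0  # mechanical threshold, kPa
    I_shift: float = 8.1  # uA/cm^2, applied while sigma >= sigma_t

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be > 0")
        for name in ("kappa_Na", "kappa_K", "kappa_A", "kappa_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MembraneState:
    """Membrane potential (mV), the five gating variables, and time (ms)."""

    V_m: float
    m: float
    h: float
    n: float
    A: float
    B: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V_m, self.m, self.h, self.n, self.A, self.B])


@dataclass(frozen=True)
class GatingKinetics:
    """Voltage-dependent kinetics of all five gating variables at one V_m.

    alpha/beta rate constants (1/ms) for m, h, n; relaxation time constants
    tau_x (ms) and steady states x_inf for all five variables.
    """

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    tau_m: float
    m_inf: float
    tau_h: float
    h_inf: float
    tau_n: float
    n_inf: float
    tau_A: float
    A_inf: float
    tau_B: float
    B_inf: float


def _vtrap(z: float) -> float:
    """z / (1 - exp(-z)) with the removable singularity at z = 0 filled in."""
    if abs(z) < 1e-7:
        return 1.0 + z / 2.0
    return z / (1.0 - math.exp(-z))


def mech_current(sigma: float, params: HHParams = HHParams()) -> float:
    """Mechanosensitive current density (uA/cm^2) for stress magnitude sigma.

    Zero below the mechanical threshold; at threshold the exponential term
    is 1 so the current steps to C_m1 + C_m3.  The Heaviside convention is
    H(0) = 1: the threshold stress itself already drives the membrane.
    """
    if sigma < 0:
        raise ValueError(f"stress magnitude must be >= 0, got {sigma}")
    if sigma < params.sigma_t:
        return 0.0
    return (
        params.C_m1 * math.exp((sigma - params.sigma_t) / (params.sigma_t * params.C_m2))
        + params.C_m3
    )


def gating_kinetics(V_m: float) -> GatingKinetics:
    """Rate constants, time constants and steady states at membrane potential V_m.

    The m and n activation rates have removable singularities (at
    V_m = -29.7 and -45.7 mV); they are evaluated by their analytic limits.
    """
    if not math.isfinite(V_m):
        raise ValueError(f"V_m must be finite, got {V_m}")
    a_m = _vtrap((V_m + 29.7) / 10.0)
    b_m = 4.0 * math.exp(-(V_m + 54.7) / 18.0)
    a_h = 0.07 * math.exp(-(V_m + 48.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(V_m + 18.0) / 10.0))
    a_n = 0.1 * _vtrap((V_m + 45.7) / 10.0)
    b_n = 0.125 * math.exp(-(V_m + 55.7) / 80.0)

    tau_A = 0.3632 + 1.158 / (1.0 + math.exp((V_m + 55.96) / 20.12))
    A_inf = (
        0.0761 * math.exp((V_m + 94.22) / 31.84) / (1.0 + math.exp((V_m + 1.17) / 28.93))
    ) ** (1.0 / 3.0)
    tau_B = 1.24 + 2.678 / (1.0 + math.exp((V_m + 50.0) / 16.027))
    B_inf = (1.0 / (1.0 + math.exp((V_m + 53.3) / 14.54))) ** 4

    return GatingKinetics(
        alpha_m=a_m,
        beta_m=b_m,
        alpha_h=a_h,
        beta_h=b_h,
        alpha_n=a_n,
        beta_n=b_n,
        tau_m=1.0 / (a_m + b_m),
        m_inf=a_m / (a_m + b_m),
        tau_h=1.0 / (a_h + b_h),
        h_inf=a_h / (a_h + b_h),
        tau_n=1.0 / (a_n + b_n),
        n_inf=a_n / (a_n + b_n),
        tau_A=tau_A,
        A_inf=A_inf,
        tau_B=tau_B,
        B_inf=B_inf,
    )


def membrane_rhs(state: MembraneState, sigma: float, params: HHParams = HHParams()):
    """Time derivatives of (V_m, m, h, n, A, B) at the given state and stress."""
    i_ext = mech_current(sigma, params) + (params.I_shift if sigma >= params.sigma_t else 0.0)
    return _rhs_tuple(
        state.V_m, state.m, state.h, state.n, state.A, state.B, i_ext, params
    )


def _rhs_tuple(V, m, h, n, A, B, i_ext, p: HHParams):
    k = gating_kinetics(V)
    I_Na = p.kappa_Na * m**3 * h * (V - p.E_Na)
    I_K = p.kappa_K * n**4 * (V - p.E_K)
    I_A = p.kappa_A * A**3 * B * (V - p.E_A)
    I_L = p.kappa_L * (V - p.E_L)
    dV = (i_ext - (I_Na + I_K + I_A + I_L)) / p.C_m
    return (
        dV,
        (k.m_inf - m) / k.tau_m,
        (k.h_inf - h) / k.tau_h,
        (k.n_inf - n) / k.tau_n,
        (k.A_inf - A) / k.tau_A,
        (k.B_inf - B) / k.tau_B,
    )


def resting_potential(params: HHParams = HHParams()) -> float:
    """Zero-stimulus resting potential, by root-finding on the steady-state current.

    With gates pinned at x_inf(V), the membrane current balance
    I_Na + I_K + I_A + I_L = 0 has a unique root in (-75, -60) mV.
    """

    def net_current(V: float) -> float:
        k = gating_kinetics(V)
        return (
            params.kappa_Na * k.m_inf**3 * k.h_inf * (V - params.E_Na)
            + params.kappa_K * k.n_inf**4 * (V - params.E_K)
            + params.kappa_A * k.A_inf**3 * k.B_inf * (V - params.E_A)
            + params.kappa_L * (V - params.E_L)
        )

    return brentq(net_current, -75.0, -60.0, xtol=1e-10)


def initial_state(V0: float = -68.0) -> MembraneState:
    """Default initial condition: V_m = V0 with gates at their steady state."""
    k = gating_kinetics(V0)
    return MembraneState(V_m=V0, m=k.m_inf, h=k.h_inf, n=k.n_inf, A=k.A_inf, B=k.B_inf)


@dataclass
class MembraneTrace:
    """Fixed-step membrane trajectory: time base plus all six state variables."""

    t: np.ndarray  # ms
    V_m: np.ndarray  # mV
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    A: np.ndarray
    B: np.ndarray
    dt: float
    sigma: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(t_ms=self.t, V_m_mV=self.V_m, m=self.m, h=self.h, n=self.n, A=self.A, B=self.B)
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_membrane(
    sigma: float,
    params: HHParams = HHParams(),
    duration: float = 1200.0,
    dt: float = 0.01,
    initial: MembraneState | None = None,
) -> MembraneTrace:
    """Integrate the membrane ODEs with classical fixed-step 4th-order Runge-Kutta.

    Parameters
    ----------
    sigma : float
        Stress magnitude at the nociceptor, kPa (constant over the run).
    duration : float
        Simulated time, ms.
    dt : float
        Step size, ms; must satisfy 0 < dt <= 0.05 for the fast sodium
        kinetics to be resolved.
    initial : MembraneState, optional
        Starting state; defaults to V_m = -68 mV with gates at steady state.

    Returns
    -------
    MembraneTrace
        State sampled at every step (duration/dt + 1 points).  Deterministic
        for fixed inputs.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 < dt <= 0.05):
        raise ValueError(f"dt must satisfy 0 < dt <= 0.05 ms, got {dt}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if initial is None:
        initial = initial_state()

    p = params
    i_ext = mech_current(sigma, p) + (p.I_shift if sigma >= p.sigma_t else 0.0)
    n_steps = int(round(duration / dt))

    out = np.empty((n_steps + 1, 6))
    V, m, h, n, A, B = initial.V_m, initial.m, initial.h, initial.n, initial.A, initial.B
    out[0] = (V, m, h, n, A, B)

    # Locals for speed: this loop dominates the pipeline runtime.
    exp = math.exp
    kNa, kK, kA, kL = p.kappa_Na, p.kappa_K, p.kappa_A, p.kappa_L
    ENa, EK, EA, EL = p.E_Na, p.E_K, p.E_A, p.E_L
    Cm = p.C_m

    def f(V, m, h, n, A, B):
        z = (V + 29.7) / 10.0
        a_m = (1.0 + z / 2.0) if abs(z) < 1e-7 else z / (1.0 - exp(-z))
        b_m = 4.0 * exp(-(V + 54.7) / 18.0)
        a_h = 0.07 * exp(-(V + 48.0) / 20.0)
        b_h = 1.0 / (1.0 + exp(-(V + 18.0) / 10.0))
        z = (V + 45.7) / 10.0
        a_n = 0.1 * ((1.0 + z / 2.0) if abs(z) < 1e-7 else z / (1.0 - exp(-z)))
        b_n = 0.125 * exp(-(V + 55.7) / 80.0)
        tau_A = 0.3632 + 1.158 / (1.0 + exp((V + 55.96) / 20.12))
        A_inf = (
            0.0761 * exp((V + 94.22) / 31.84) / (1.0 + exp((V + 1.17) / 28.93))
        ) ** (1.0 / 3.0)
        tau_B = 1.24 + 2.678 / (1.0 + exp((V + 50.0) / 16.027))
        B_inf = (1.0 / (1.0 + exp((V + 53.3) / 14.54))) ** 4
        dV = (
            i_ext
            - kNa * m * m * m * h * (V - ENa)
            - kK * n * n * n * n * (V - EK)
            - kA * A * A * A * B * (V - EA)
            - kL * (V - EL)
        ) / Cm
        return (
            dV,
            a_m * (1.0 - m) - b_m * m,
            a_h * (1.0 - h) - b_h * h,
            a_n * (1.0 - n) - b_n * n,
            (A_inf - A) / tau_A,
            (B_inf - B) / tau_B,
        )

    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(1, n_steps + 1):
        k1 = f(V, m, h, n, A, B)
        k2 = f(
            V + half * k1[0], m + half * k1[1], h + half * k1[2],
            n + half * k1[3], A + half * k1[4], B + half * k1[5],
        )
        k3 = f(
            V + half * k2[0], m + half * k2[1], h + half * k2[2],
            n + half * k2[3], A + half * k2[4], B + half * k2[5],
        )
        k4 = f(
            V + dt * k3[0], m + dt * k3[1], h + dt * k3[2],
            n + dt * k3[3], A + dt * k3[4], B + dt * k3[5],
        )
        V += sixth * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
        m += sixth * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
        h += sixth * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
        n += sixth * (k1[3] + 2.0 * (k2[3] + k3[3]) + k4[3])
        A += sixth * (k1[4] + 2.0 * (k2[4] + k3[4]) + k4[4])
        B += sixth * (k1[5] + 2.0 * (k2[5] + k3[5]) + k4[5])
        if not (math.isfinite(V) and -500.0 < V < 500.0):
            raise FloatingPointError(
                f"membrane integration diverged at step {i} (t = {i * dt:.3f} ms): V_m = {V}"
            )
        out[i] = (V, m, h, n, A, B)

    t = np.arange(n_steps + 1) * dt
    return MembraneTrace(
        t=t, V_m=out[:, 0], m=out[:, 1], h=out[:, 2], n=out[:, 3],
        A=out[:, 4], B=out[:, 5], dt=dt, sigma=sigma,
    )


@dataclass(frozen=True)
class SpikeSummary:
    """Firing-rate summary of a membrane trace."""

    frequency: float  # Hz; 0 when no sustained oscillation is detected
    n_spikes: int  # upward 0-mV crossings in the analysis window
    method: str  # "fft" or "spike_count"


# A spiking membrane swings tens of mV; a post-transient peak-to-peak range
# below this is a settling tail, not an oscillation.
_QUIESCENT_RANGE_MV = 1.0
# A non-DC spectral peak must exceed this fraction of the signal RMS to count.
_FFT_NOISE_FLOOR = 0.05
# A spike train spreads power across harmonics of comparable magnitude; the
# fundamental is taken as the lowest local spectral peak within this fraction
# of the strongest non-DC peak.
_HARMONIC_PEAK_FRACTION = 0.5


def _upward_crossing_times(t: np.ndarray, v: np.ndarray, level: float = 0.0) -> np.ndarray:
    above = v > level
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    return t[idx]


def firing_frequency(
    trace: MembraneTrace,
    method: str = "fft",
    transient: float = 200.0,
) -> SpikeSummary:
    """Firing frequency (Hz) of a membrane trace after transient removal.

    ``fft``: subtract the mean over the post-transient window and return the
    frequency of the largest non-DC peak of the discrete Fourier transform;
    the trace is declared quiescent (frequency 0) when its peak-to-peak
    range is below 1 mV or the peak amplitude is below 5% of the signal RMS.
    ``spike_count``: upward crossings of 0 mV; the rate is the number of
    inter-spike intervals divided by the time they span, which avoids the
    +-1 edge error of a plain count over the window.  For periodic spiking
    the two methods agree within one spectral bin.
    """
    if method not in ("fft", "spike_count"):
        raise ValueError(f"unknown method {method!r}")
    window_ms = trace.t[-1] - transient
    if window_ms < 800.0:
        raise ValueError(
            f"post-transient window is {window_ms:.0f} ms; >= 800 ms required "
            "for stable frequency estimation"
        )
    i0 = int(np.searchsorted(trace.t, transient))
    v = trace.V_m[i0:]
    spike_times = _upward_crossing_times(trace.t[i0:], v)
    n_spikes = int(spike_times.size)

    if np.ptp(v) < _QUIESCENT_RANGE_MV:
        return SpikeSummary(frequency=0.0, n_spikes=0, method=method)

    if method == "spike_count":
        if n_spikes < 2:
            return SpikeSummary(frequency=0.0, n_spikes=n_spikes, method=method)
        span_s = (spike_times[-1] - spike_times[0]) / 1000.0
        return SpikeSummary(
            frequency=(n_spikes - 1) / span_s, n_spikes=n_spikes, method=method
        )

    x = v - v.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=trace.dt / 1000.0)  # Hz
    k_max = 1 + int(np.argmax(spec[1:]))
    peak_amplitude = 2.0 * spec[k_max] / x.size
    rms = float(np.sqrt(np.mean(x * x)))
    if peak_amplitude < _FFT_NOISE_FLOOR * rms:
        return SpikeSummary(frequency=0.0, n_spikes=0, method=method)
    # Spike-train spectra carry near-equal power at integer harmonics; report
    # the fundamental: the lowest local peak comparable to the strongest one.
    thresh = _HARMONIC_PEAK_FRACTION * spec[k_max]
    local_max = (spec[1:-1] >= spec[:-2]) & (spec[1:-1] >= spec[2:])
    candidates = np.nonzero(local_max & (spec[1:-1] >= thresh))[0] + 1
    k = int(candidates[0]) if candidates.size else k_max
    return SpikeSummary(frequency=float(freqs[k]), n_spikes=n_spikes, method=method)


def firing_onset_stress(
    lo: float = 0.0,
    hi: float = 40.0,
    tol: float = 0.5,
    params: HHParams = HHParams(),
    duration: float = 1200.0,
    dt: float = 0.01,
    transient: float = 200.0,
) -> float:
    """Smallest stress magnitude that elicits sustained firing, by bisection.

    Brackets the onset between a silent lower bound and a firing upper bound
    and bisects until the interval is below ``tol`` (kPa); returns the
    midpoint.  The model's rheobase-like onset sits at the mechanical
    threshold sigma_t, where the stimulus current switches on.
    """

    def fires(sigma: float) -> bool:
        trace = simulate_membrane(sigma, params, duration=duration, dt=dt)
        return firing_frequency(trace, transient=transient).frequency > 0.0

    if fires(lo):
        raise ValueError(f"lower bound {lo} kPa already fires; widen the bracket")
    if not fires(hi):
        raise ValueError(f"upper bound {hi} kPa is silent; widen the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
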