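"""Gate-control-theory circuit: modulation and perception of the nociceptive signal.

Four coupled cells of the dorsal horn / midbrain loop: an inhibitory
substantia gelatinosa (SG) interneuron (potential ``V_i``), an excitatory SG
interneuron (``V_e``), the central transmission cell or T-cell (``V_t``),
and a midbrain cell providing descending feedback (``V_b``).  Each cell
relaxes toward its resting potential (-70 mV) with time constant 0.7 and is
pushed by saturating (tanh) synaptic drives from the fibre inputs and the
other cells:

    0.7 dVi/dt = -(Vi + 70) + 60 tanh(theta_li * x_l) + 40 tanh(f(Vb))
    0.7 dVe/dt = -(Ve + 70) + 40 tanh(theta_se * x_s) [1 + 3 tanh(4 f(Ve))]
    0.7 dVt/dt = -(Vt + 70) + 40 tanh((1-theta_se) x_s) + 40 tanh((1-theta_li) x_l)
                 + 40 tanh(f(Ve)) - 40 tanh(f(Vi)) - 40 tanh(f(Vb))
    0.7 dVb/dt = -(Vb + 70) + 40 tanh(f(Vt))

with the firing-rate output function f(V) = (V - V_thr - V_0) H(V - V_thr),
V_thr = -55 mV, V_0 = -70 mV.  ``x_l`` and ``x_s`` are the large- and
small-fibre firing rates (Hz); for compression pain the noxious signal
travels on the small fibres, so x_l = 0 and x_s is the nociceptor firing
frequency.  Pain is signalled when the T-cell output exceeds V_thr.

The drive f jumps from 0 to ~70 at threshold, which saturates every tanh it
feeds: above onset the circuit behaves like a relay and can settle into a
sustained oscillation rather than a smooth plateau.  The output statistic
:func:`t_cell_output` therefore reports the late-window maximum of V_t,
which equals the plateau when one exists and flags the oscillatory case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GCTParams",
    "GCTState",
    "FiberInput",
    "GCTTrace",
    "TCellOutput",
    "fiber_drive",
    "gct_rhs",
    "simulate_gct",
    "t_cell_output",
    "pain_decision",
]


@dataclass(frozen=True)
class GCTParams:
    """Parameters of the four-cell gate-control circuit.

    theta_li / theta_se: fraction of large-/small-fibre excitation delivered
    to the inhibitory / excitatory SG cell (the complements reach the
    T-cell directly).  tau is the common relaxation time constant of all
    four cells (model time units).  V_0 is the shared initial/resting
    potential and V_thr the pain threshold.  w_l and w_s scale the
    large-fibre drive on the inhibitory SG cell and all other synaptic
    terms.  ``x_s_scale`` rescales the incoming small-fibre rate (1.0 means
    the nociceptor frequency is used in Hz).  ``fiber_drive_variant``
    selects the output function: "offset" is the literal
    (V - V_thr - V_0) H(V - V_thr) form; "linear" is the conventional
    (V - V_thr) H(V - V_thr) alternative.
    """

    theta_li: float = 0.8
    theta_se: float = 0.8
    tau: float = 0.7
    V_0: float = -70.0
    V_thr: float = -55.0
    w_l: float = 60.0  # mV, large-fibre weight on the inhibitory SG cell
    w_s: float = 40.0  # mV, weight of every other synaptic term
    x_s_scale: float = 1.0
    fiber_drive_variant: str = "offset"

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_li <= 1.0 and 0.0 <= self.theta_se <= 1.0):
            raise ValueError("transmission proportions theta must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.V_thr <= self.V_0:
            raise ValueError("pain threshold V_thr must exceed the resting potential V_0")
        if self.fiber_drive_variant not in ("offset", "linear"):
            raise ValueError("fiber_drive_variant must be 'offset' or 'linear'")


@dataclass
class GCTState:
    """Potentials (mV) of the four cells and the model time."""

    V_i: float
    V_e: float
    V_t: float
    V_b: float
    t: float = 0.0


@dataclass(frozen=True)
class FiberInput:
    """Large- and small-fibre firing rates (Hz) entering the gate."""

    x_l: float = 0.0
    x_s: float = 0.0

    def __post_init__(self) -> None:
        if self.x_l < 0 or self.x_s < 0:
            raise ValueError("fibre rates must be >= 0")


def fiber_drive(V_j: float, params: GCTParams = GCTParams()) -> float:
    """Firing-rate output f(V) of a gate cell.

    Strictly zero at and below the threshold (H(0) = 0: the signal passes
    only when the potential *exceeds* V_thr).  In the "offset" form the
    drive jumps discontinuously to -V_0 + (V_j - V_thr) ~ 70 just above
    threshold, which saturates the downstream tanh terms.
    """
    if not math.isfinite(V_j):
        raise ValueError(f"V_j must be finite, got {V_j}")
    if V_j <= params.V_thr:
        return 0.0
    if params.fiber_drive_variant == "linear":
        return V_j - params.V_thr
    return V_j - params.V_thr - params.V_0


def gct_rhs(
    state: GCTState, fibers: FiberInput, params: GCTParams = GCTParams()
) -> tuple[float, float, float, float]:
    """Time derivatives (dVi, dVe, dVt, dVb) of the four cell potentials."""
    p = params
    x_l = fibers.x_l
    x_s = fibers.x_s * p.x_s_scale
    f_i = fiber_drive(state.V_i, p)
    f_e = fiber_drive(state.V_e, p)
    f_t = fiber_drive(state.V_t, p)
    f_b = fiber_drive(state.V_b, p)
    rest = -p.V_0  # leak pulls each potential back to V_0
    dVi = (-(state.V_i + rest) + p.w_l * math.tanh(p.theta_li * x_l)
           + p.w_s * math.tanh(f_b)) / p.tau
    dVe = (-(state.V_e + rest)
           + p.w_s * math.tanh(p.theta_se * x_s) * (1.0 + 3.0 * math.tanh(4.0 * f_e))) / p.tau
    dVt = (-(state.V_t + rest)
           + p.w_s * math.tanh((1.0 - p.theta_se) * x_s)
           + p.w_s * math.tanh((1.0 - p.theta_li) * x_l)
           + p.w_s * math.tanh(f_e)
           - p.w_s * math.tanh(f_i)
           - p.w_s * math.tanh(f_b)) / p.tau
    dVb = (-(state.V_b + rest) + p.w_s * math.tanh(f_t)) / p.tau
    return (dVi, dVe, dVt, dVb)


@dataclass
class GCTTrace:
    """Fixed-step trajectory of the four gate-circuit potentials."""

    t: np.ndarray
    V_i: np.ndarray
    V_e: np.ndarray
    V_t: np.ndarray
    V_b: np.ndarray
    dt: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(t=self.t, V_i_mV=self.V_i, V_e_mV=self.V_e,
                 V_t_mV=self.V_t, V_b_mV=self.V_b)
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_gct(
    fibers: FiberInput,
    params: GCTParams = GCTParams(),
    duration: float = 50.0,
    dt: float = 0.005,
) -> GCTTrace:
    """Integrate the gate circuit with fixed-step 4th-order Runge-Kutta.

    Starts from the common resting state (all potentials at V_0 = -70 mV);
    deterministic for fixed inputs.  Durations are in the circuit's model
    time units (the 0.7 relaxation constant sets the scale).
    """
    if duration < 50.0:
        raise ValueError("duration must be >= 50 time units for a settled output")
    if not (0 < dt <= 0.01):
        raise ValueError(f"dt must satisfy 0 < dt <= 0.01, got {dt}")

    n_steps = int(round(duration / dt))
    out = np.empty((n_steps + 1, 4))
    y = GCTState(V_i=params.V_0, V_e=params.V_0, V_t=params.V_0, V_b=params.V_0)
    out[0] = (y.V_i, y.V_e, y.V_t, y.V_b)

    def f(vi, ve, vt, vb):
        return gct_rhs(GCTState(V_i=vi, V_e=ve, V_t=vt, V_b=vb), fibers, params)

    vi, ve, vt, vb = (params.V_0,) * 4
    half, sixth = dt / 2.0, dt / 6.0
    for i in range(1, n_steps + 1):
        k1 = f(vi, ve, vt, vb)
        k2 = f(vi + half * k1[0], ve + half * k1[1], vt + half * k1[2], vb + half * k1[3])
        k3 = f(vi + half * k2[0], ve + half * k2[1], vt + half * k2[2], vb + half * k2[3])
        k4 = f(vi + dt * k3[0], ve + dt * k3[1], vt + dt * k3[2], vb + dt * k3[3])
        vi += sixth * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
        ve += sixth * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
        vt += sixth * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
        vb += sixth * (k1[3] + 2.0 * (k2[3] + k3[3]) + k4[3])
        if not all(map(math.isfinite, (vi, ve, vt, vb))):
            raise FloatingPointError(
                f"gate-circuit integration diverged at step {i} (t = {i * dt:.3f})"
            )
        out[i] = (vi, ve, vt, vb)

    t = np.arange(n_steps + 1) * dt
    return GCTTrace(t=t, V_i=out[:, 0], V_e=out[:, 1], V_t=out[:, 2], V_b=out[:, 3], dt=dt)


@dataclass(frozen=True)
class TCellOutput:
    """Late-window summary of the T-cell potential."""

    value: float  # mV, maximum of V_t over the final half of the trajectory
    oscillatory: bool  # late-window peak-to-trough range exceeds 1 mV


# Late-window V_t swings above this range are reported as oscillatory rather
# than a plateau.
_OSCILLATION_RANGE_MV = 1.0


def t_cell_output(traj: GCTTrace) -> TCellOutput:
    """Pain statistic: maximum T-cell potential over the final half of the run.

    Equals the plateau value when the circuit settles and remains meaningful
    (the per-cycle peak) when the relay-like feedback sustains an
    oscillation; the ``oscillatory`` flag separates the two regimes.
    """
    if traj.t[-1] - traj.t[0] < 50.0:
        raise ValueError("trajectory must cover >= 50 time units")
    i0 = int(np.searchsorted(traj.t, traj.t[0] + (traj.t[-1] - traj.t[0]) / 2.0))
    late = traj.V_t[i0:]
    return TCellOutput(
        value=float(late.max()),
        oscillatory=bool(np.ptp(late) > _OSCILLATION_RANGE_MV),
    )


def pain_decision(output: float, params: GCTParams = GCTParams()) -> bool:
    """True iff the T-cell output strictly exceeds the pain threshold (-55 mV)."""
    return output > params.V_thr
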