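"""Three-state GABA_A receptor gating model.

The channel is described by the scheme ``C0 <-> C1 <-> O``: an unbound
closed state, a GABA-bound closed state, and an open state.  Transitions
are governed by four rate constants (binding ``k1``, unbinding ``k2``,
opening ``k3``, closing ``k4``) and the synaptic-cleft transmitter
transient ``[GABA](t) = g_max * exp(-t / tau)``.  The model deliberately
omits desensitized states: it is the simplest scheme that reproduces the
rise/decay kinetics, peak open probability and steady-state GABA
sensitivity of dorsal-horn miniature IPSCs without over-fitting.

Two parameter presets are shipped: ``SHAM`` (control animals) and ``PNI``
(peripheral nerve injury), the latter with lower GABA affinity and slower
closing, reproducing the slower decay and right-shifted GABA EC50 seen
after injury.

Unit convention: ``k1`` is a second-order rate in 1/(mM*ms) — it always
multiplies a concentration in mM — while ``k2``..``k4`` are first-order
rates in 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "GatingParams",
    "TransmitterPulse",
    "GatingTrajectory",
    "EventSummary",
    "GabaDoseCurve",
    "TrainDepressionFit",
    "GatingTargets",
    "SHAM",
    "PNI",
    "DEFAULT_PULSE",
    "simulate_gating",
    "steady_state_open_fraction",
    "gaba_dose_response",
    "summarize_event",
    "fit_gating_constraints",
    "conductance_timecourse",
    "fit_train_depression",
]


@dataclass(frozen=True)
class GatingParams:
    """Rate constants of the C0 <-> C1 <-> O scheme.

    k1 : binding rate, 1/(mM*ms); k2 : unbinding rate, 1/ms;
    k3 : opening rate, 1/ms; k4 : closing rate, 1/ms.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def max_open_fraction(self) -> float:
        """Open fraction at saturating GABA, k3 / (k3 + k4)."""
        return self.k3 / (self.k3 + self.k4)

    @property
    def gaba_ec50(self) -> float:
        """Closed-form steady-state GABA EC50 in mM, k2*k4 / (k1*(k3+k4))."""
        return self.k2 * self.k4 / (self.k1 * (self.k3 + self.k4))


@dataclass(frozen=True)
class TransmitterPulse:
    """Exponential synaptic GABA transient: g_max (mM) decaying with tau (ms)."""

    g_max: float = 0.63
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def concentration(self, t):
        return self.g_max * np.exp(-np.asarray(t, dtype=float) / self.tau)


#: Printed control preset.
SHAM = GatingParams(k1=40.0, k2=0.8, k3=1.0, k4=0.15, label="sham")
#: Printed nerve-injury preset (lower affinity, slower closing).
PNI = GatingParams(k1=11.2, k2=0.8, k3=0.43, k4=0.06, label="pni")
#: Default synaptic transient (0.63 mM peak, 1 ms decay).
DEFAULT_PULSE = TransmitterPulse()


@dataclass
class GatingTrajectory:
    """State-fraction time courses on a uniform grid (ms)."""

    t: np.ndarray
    c0: np.ndarray
    c1: np.ndarray
    o: np.ndarray
    params: Optional[GatingParams] = None

    def conservation_error(self) -> float:
        return float(np.abs(self.c0 + self.c1 + self.o - 1.0).max())


@dataclass
class EventSummary:
    peak_open_fraction: float
    time_to_peak: float  # ms
    rise_10_90: float  # ms
    decay_tau: float  # ms


@dataclass
class GabaDoseCurve:
    concentration: np.ndarray  # mM
    open_fraction: np.ndarray
    ec50: float  # mM
    o_max: float


@dataclass
class TrainDepressionFit:
    normalized: np.ndarray
    plateau: float
    decay_pulses: float
    degenerate: bool = False


def simulate_gating(
    params: GatingParams,
    pulse: TransmitterPulse = DEFAULT_PULSE,
    duration: float = 120.0,
    rtol: float = 1e-8,
    dt: float = 0.05,
) -> GatingTrajectory:
    """Integrate the gating ODEs driven by an exponential GABA transient.

    The system is

        dC0/dt = -k1*[G]*C0 + k2*C1
        dC1/dt =  k1*[G]*C0 - (k2 + k3)*C1 + k4*O
        dO/dt  =  k3*C1 - k4*O

    with [G](t) = g_max * exp(-t/tau) and all channels initially in C0.
    Output is sampled every ``dt`` ms.
    """
    if duration < 10.0 * pulse.tau:
        raise ValueError("duration must be at least 10x the transmitter tau")
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    g_max, tau = pulse.g_max, pulse.tau

    def rhs(t, y):
        c0, c1, o = y
        g = g_max * np.exp(-t / tau)
        return (
            -k1 * g * c0 + k2 * c1,
            k1 * g * c0 - (k2 + k3) * c1 + k4 * o,
            k3 * c1 - k4 * o,
        )

    t_eval = np.arange(0.0, duration + dt / 2, dt)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        (1.0, 0.0, 0.0),
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=rtol * 1e-2,
    )
    if not sol.success:
        raise RuntimeError(f"gating integration failed: {sol.message}")
    return GatingTrajectory(t=sol.t, c0=sol.y[0], c1=sol.y[1], o=sol.y[2], params=params)


def steady_state_open_fraction(params: GatingParams, g_const) -> np.ndarray | float:
    """Open fraction at steady state under a constant GABA concentration (mM).

    Closed form: O = k1*G*k3 / (k2*k4 + k1*G*(k3 + k4)).
    """
    g = np.asarray(g_const, dtype=float)
    if np.any(g < 0):
        raise ValueError("GABA concentration must be >= 0")
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    out = k1 * g * k3 / (k2 * k4 + k1 * g * (k3 + k4))
    return float(out) if np.isscalar(g_const) else out


def gaba_dose_response(params: GatingParams, grid: Sequence[float]) -> GabaDoseCurve:
    """Steady-state open fraction across a concentration grid (mM)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    return GabaDoseCurve(
        concentration=grid,
        open_fraction=steady_state_open_fraction(params, grid),
        ec50=params.gaba_ec50,
        o_max=params.max_open_fraction,
    )


def summarize_event(
    traj: GatingTrajectory, decay_floor_frac: float = 0.05
) -> EventSummary:
    """Peak, 10-90% rise time and single-exponential decay of an event.

    The decay constant comes from a zero-offset exponential fit over the
    window from the peak to the last sample above ``decay_floor_frac`` of
    the peak (states relax to zero once the transmitter is gone, so no
    free offset is fitted).
    """
    o = np.asarray(traj.o)
    i_peak = int(np.argmax(o))
    if i_peak == 0 or i_peak == len(o) - 1:
        raise ValueError("open fraction has no interior peak")
    peak = float(o[i_peak])

    # 10-90 rise from threshold crossings on the rising limb
    rise = o[: i_peak + 1]
    t_rise = traj.t[: i_peak + 1]
    t10 = float(np.interp(0.1 * peak, rise, t_rise))
    t90 = float(np.interp(0.9 * peak, rise, t_rise))

    above = np.nonzero(o >= decay_floor_frac * peak)[0]
    i_end = int(above[-1])
    tt = traj.t[i_peak : i_end + 1] - traj.t[i_peak]
    yy = o[i_peak : i_end + 1]
    popt, _ = curve_fit(
        lambda x, a, tau: a * np.exp(-x / tau), tt, yy, p0=(peak, 15.0), maxfev=10000
    )
    return EventSummary(
        peak_open_fraction=peak,
        time_to_peak=float(traj.t[i_peak]),
        rise_10_90=t90 - t10,
        decay_tau=float(popt[1]),
    )


@dataclass
class GatingTargets:
    """Targets for the seven-constraint fit of the two-condition gating model.

    Times in ms; ``ec50_sham`` in mM; ``peak_reduction`` is the fractional
    reduction of the PNI peak open fraction relative to sham (the source
    constraint uses the literal figure 0.372); ``peak_min`` is the lower
    bound on the sham peak open fraction (inequality, hinge-penalized).
    """

    rise_sham: float
    decay_sham: float
    rise_pni: float
    decay_pni: float
    ec50_sham: float
    peak_reduction: float = 0.372
    peak_min: float = 0.5
    weights: Optional[np.ndarray] = None  # 7 weights, default equal

    @classmethod
    def from_presets(
        cls,
        sham: GatingParams = SHAM,
        pni: GatingParams = PNI,
        pulse: TransmitterPulse = DEFAULT_PULSE,
        **kw,
    ) -> "GatingTargets":
        """Self-consistency targets: kinetic summaries simulated from presets."""
        s = summarize_event(simulate_gating(sham, pulse))
        p = summarize_event(simulate_gating(pni, pulse))
        return cls(
            rise_sham=s.rise_10_90,
            decay_sham=s.decay_tau,
            rise_pni=p.rise_10_90,
            decay_pni=p.decay_tau,
            ec50_sham=sham.gaba_ec50,
            **kw,
        )


def fit_gating_constraints(
    targets: GatingTargets,
    shared_k2: bool = True,
    pulse: TransmitterPulse = DEFAULT_PULSE,
    x0: Optional[Sequence[float]] = None,
    duration: float = 120.0,
) -> tuple[GatingParams, GatingParams, dict]:
    """Weighted least-squares fit of the seven rate constants to seven targets.

    Free parameters (log scale): k1/k3/k4 for each condition plus a single
    shared unbinding rate k2 (or two k2 values when ``shared_k2`` is False).
    Residuals, each normalized by its target: (i-iv) rise and decay times of
    both conditions, (v) hinge penalty if the sham peak open fraction falls
    below ``peak_min``, (vi) the relative PNI-vs-sham peak reduction, and
    (vii) the sham steady-state GABA EC50.

    Returns the two fitted parameter sets and a residual report; optimizer
    failure raises rather than returning silently.
    """
    t = targets
    if x0 is None:
        x0 = [40.0, 0.8, 1.0, 0.15, 11.2, 0.43, 0.06]
        if not shared_k2:
            x0 = x0[:5] + [0.8] + x0[5:]
    logx0 = np.log(np.asarray(x0, dtype=float))
    w = np.ones(7) if t.weights is None else np.asarray(t.weights, dtype=float)

    def unpack(logp):
        p = np.exp(logp)
        if shared_k2:
            k1s, k2s, k3s, k4s, k1p, k3p, k4p = p
            k2p = k2s
        else:
            k1s, k2s, k3s, k4s, k1p, k2p, k3p, k4p = p
        return (
            GatingParams(k1s, k2s, k3s, k4s, "sham-fit"),
            GatingParams(k1p, k2p, k3p, k4p, "pni-fit"),
        )

    def residuals(logp):
        ps, pp = unpack(logp)
        ss = summarize_event(simulate_gating(ps, pulse, duration=duration))
        sp = summarize_event(simulate_gating(pp, pulse, duration=duration))
        reduction = 1.0 - sp.peak_open_fraction / ss.peak_open_fraction
        res = np.array(
            [
                (ss.rise_10_90 - t.rise_sham) / t.rise_sham,
                (ss.decay_tau - t.decay_sham) / t.decay_sham,
                (sp.rise_10_90 - t.rise_pni) / t.rise_pni,
                (sp.decay_tau - t.decay_pni) / t.decay_pni,
                max(0.0, t.peak_min - ss.peak_open_fraction) / t.peak_min,
                (reduction - t.peak_reduction) / t.peak_reduction,
                (ps.gaba_ec50 - t.ec50_sham) / t.ec50_sham,
            ]
        )
        return w * res

    fit = least_squares(residuals, logx0, xtol=1e-10, ftol=1e-12, gtol=1e-10)
    if not fit.success:
        raise RuntimeError(f"gating constraint fit did not converge: {fit.message}")
    sham_fit, pni_fit = unpack(fit.x)
    res = residuals(fit.x)
    names = [
        "rise_sham",
        "decay_sham",
        "rise_pni",
        "decay_pni",
        "peak_min_hinge",
        "peak_reduction",
        "ec50_sham",
    ]
    report = {
        "residuals": dict(zip(names, res.tolist())),
        "cost": float(fit.cost),
        "message": fit.message,
        "shared_k2": shared_k2,
    }
    return sham_fit, pni_fit, report


def conductance_timecourse(
    traj: GatingTrajectory, relative_channel_number: float = 1.0
) -> np.ndarray:
    """Relative conductance trace: open fraction scaled by channel number.

    After nerve injury the synaptic receptor count is 37.2% larger
    (``relative_channel_number = 1.372``), so the same open fraction
    produces a proportionally larger conductance.
    """
    if relative_channel_number <= 0:
        raise ValueError("relative_channel_number must be > 0")
    return relative_channel_number * np.asarray(traj.o)


def fit_train_depression(amplitudes: Sequence[float]) -> TrainDepressionFit:
    """One-phase decay fit of eIPSC amplitudes along a stimulus train.

    Amplitudes are normalized to the mean of the first three responses,
    then fitted with ``A(n) = c * (plateau + (1 - plateau) * exp(-n /
    tau_n))`` where ``n`` counts pulses from the first.  The free scale
    ``c`` absorbs the normalization (the first three pulses already
    decay, so the first-pulse response is not exactly 1 after
    normalization); the reported plateau is the depressed steady level as
    a fraction of the first-pulse response, independent of scaling.  A
    constant train is degenerate (plateau 1, flagged) rather than an
    error.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size < 5:
        raise ValueError("need at least 5 pulses")
    norm = amp / amp[:3].mean()
    n = np.arange(amp.size, dtype=float)
    if np.allclose(norm, norm[0]):
        return TrainDepressionFit(
            normalized=norm, plateau=1.0, decay_pulses=np.inf, degenerate=True
        )

    def model(x, c, plateau, tau):
        return c * (plateau + (1.0 - plateau) * np.exp(-x / tau))

    popt, _ = curve_fit(
        model,
        n,
        norm,
        p0=(1.0, max(norm[-1], 1e-3), max(amp.size / 4.0, 1.0)),
        bounds=((1e-6, 0.0, 1e-6), (10.0, 2.0, 1e4)),
        maxfev=10000,
    )
    return TrainDepressionFit(
        normalized=norm, plateau=float(popt[1]), decay_pulses=float(popt[2])
    )
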