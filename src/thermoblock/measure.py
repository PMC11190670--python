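"""Scalar observables extracted from simulation traces.

Spike detection, conduction velocity from half-maximum arrival times, the
exponential time constant of the action-potential foot, peak rates of rise
and fall, the RaCm cable composition, steady-state length constants, charge
transfer and spike-train statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cable import AxonModel, StimulusProtocol, SimulationResult

__all__ = [
    "APWaveform",
    "ProtocolOutcome",
    "classify_block",
    "conduction_velocity",
    "arrival_time",
    "foot_time_constant",
    "rates_of_change",
    "racm_estimate",
    "length_constant",
    "length_constant_from_profile",
    "charge_transfer",
    "spike_train_stats",
]

BLOCK_THRESHOLD_MV = -60.0
SPIKE_REFRACTORY_MS = 2.0


@dataclass
class APWaveform:
    """Single-point voltage time profile V(t) at a probe position."""

    x_mm: float
    t: np.ndarray
    v: np.ndarray
    v_rest: float

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if self.t.size != self.v.size or self.t.size == 0:
            raise ValueError("time and voltage arrays must be equal, non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @classmethod
    def from_result(cls, result: SimulationResult, x_mm: float) -> "APWaveform":
        v = result.probe(x_mm)
        key = min(result.probe_v, key=lambda p: abs(p - x_mm))
        j = int(np.argmin(np.abs(result.x_mm - key)))
        return cls(x_mm=key, t=result.t, v=v, v_rest=float(result.v_rest[j]))


@dataclass
class ProtocolOutcome:
    """A named scalar measurement with the settings that produced it."""

    name: str
    value: float
    units: str
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError(f"outcome {self.name!r} is not finite")


def classify_block(wave: APWaveform, threshold: float = BLOCK_THRESHOLD_MV) -> bool:
    """Blocked iff the potential never exceeds the threshold (<= convention,
    i.e. touching the threshold exactly still counts as blocked)."""
    if wave.v.size == 0:
        raise ValueError("empty trace")
    return bool(np.max(wave.v) <= threshold)


def arrival_time(wave: APWaveform) -> float:
    """Half-maximum arrival time (ms), linearly interpolated.

    Half-maximum is measured between the waveform's resting level and its
    peak. Raises if the trace never crosses it (signals block).
    """
    v, t = wave.v, wave.t
    v_half = wave.v_rest + 0.5 * (np.max(v) - wave.v_rest)
    above = v >= v_half
    if not above.any() or np.max(v) <= wave.v_rest + 1.0:
        raise ValueError(f"no action potential at probe x={wave.x_mm} mm")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (v_half - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def conduction_velocity(result: SimulationResult, x1: float, x2: float) -> float:
    """Conduction velocity (m/s) between two recorded probes.

    theta = (x2-x1) / (t2-t1) with arrival defined at the half-maximum
    crossing of each probe's waveform; mm/ms = m/s.
    """
    w1 = APWaveform.from_result(result, x1)
    w2 = APWaveform.from_result(result, x2)
    t1, t2 = arrival_time(w1), arrival_time(w2)
    if t2 == t1:
        raise ValueError("identical arrival times; probes too close")
    return float((w2.x_mm - w1.x_mm) / (t2 - t1))


def _foot_window(wave: APWaveform, prior_ms: float = 0.1):
    t, v = wave.t, wave.v
    onset_mask = v > wave.v_rest + 0.01 * abs(wave.v_rest)
    if not onset_mask.any():
        raise ValueError("no AP upstroke in waveform")
    onset = int(np.argmax(onset_mask))
    peak = int(np.argmax(v))
    dvdt = np.gradient(v, t)
    dmax = int(np.argmax(dvdt[: peak + 1]))
    if dmax <= onset:
        raise ValueError("degenerate foot window (max derivative before onset)")
    end = onset + (dmax - onset) // 2
    dt = float(np.median(np.diff(t)))
    start = max(onset - int(round(prior_ms / dt)), 0)
    return start, end


def foot_time_constant(wave: APWaveform) -> float:
    """Exponential time constant of the action-potential foot, in us.

    The foot window runs from 0.1 ms before the onset (the time the
    potential first exceeds rest by 1% of its magnitude) to halfway between
    onset and the time of maximum dV/dt. A least-squares fit of
    V(t) = V0 + A exp(t/tau) over that window yields tau.
    """
    start, end = _foot_window(wave)
    tt = wave.t[start : end + 1] - wave.t[start]
    vv = wave.v[start : end + 1]
    vr = wave.v_rest
    above = vv > vr + 1e-3
    if above.sum() < 3:
        raise ValueError("too few points above rest in foot window")
    slope = np.polyfit(tt[above], np.log(vv[above] - vr + 1e-12), 1)[0]
    if slope <= 0:
        raise ValueError("foot is not rising; cannot fit exponential")
    tau0 = 1.0 / slope
    a0 = (vv[-1] - vr) * np.exp(-tt[-1] / tau0)

    def model(x, v0, a, tau):
        return v0 + a * np.exp(x / tau)

    try:
        popt, _ = curve_fit(model, tt, vv, p0=(vr, a0, tau0), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"foot fit failed to converge (window {wave.t[start]:.3f}-"
            f"{wave.t[end]:.3f} ms, tau0={tau0:.4f} ms)") from exc
    tau_ms = float(popt[2])
    if tau_ms <= 0:
        raise RuntimeError("foot fit returned non-positive time constant")
    return tau_ms * 1e3


def rates_of_change(wave: APWaveform):
    """(max rate of rise, max rate of fall) in V/s, both positive.

    Central-difference derivative; rise is the maximum before the AP peak,
    fall the maximum magnitude after it.
    """
    v, t = wave.v, wave.t
    peak = int(np.argmax(v))
    if np.max(v) <= wave.v_rest + 10.0:
        raise ValueError("no action potential in waveform")
    dvdt = np.gradient(v, t)  # mV/ms = V/s
    rise = float(np.max(dvdt[: peak + 1]))
    fall = float(np.max(-dvdt[peak:]))
    return rise, fall


def racm_estimate(tau_foot_us: float, theta_m_per_s: float, radius_um: float) -> float:
    """RaCm = r / (2 tau_foot theta^2) in SI (ohm farad / m)."""
    if tau_foot_us <= 0 or theta_m_per_s <= 0 or radius_um <= 0:
        raise ValueError("all inputs must be positive")
    return radius_um * 1e-6 / (2.0 * tau_foot_us * 1e-6 * theta_m_per_s ** 2)


def length_constant_from_profile(x_mm, dv, x0_mm: float,
                                 direction: str = "right") -> float:
    """Distance (mm) from x0 at which |dv| first decays to 1/e of its value
    at x0, linearly interpolated; scans in the given direction."""
    x_mm = np.asarray(x_mm, float)
    dv = np.abs(np.asarray(dv, float))
    j0 = int(np.argmin(np.abs(x_mm - x0_mm)))
    if direction == "left":
        dv = dv[::-1]
        x_mm = -x_mm[::-1]
        j0 = dv.size - 1 - j0
    elif direction != "right":
        raise ValueError("direction must be 'left' or 'right'")
    target = dv[j0] / np.e
    seg = dv[j0:]
    below = seg <= target
    if not below.any():
        raise ValueError("1/e level not reached before the end of the axon")
    i = int(np.argmax(below))
    if i == 0:
        return 0.0
    frac = (seg[i - 1] - target) / (seg[i - 1] - seg[i])
    xs = x_mm[j0:]
    return float(xs[i - 1] + frac * (xs[i] - xs[i - 1]) - x_mm[j0])


def length_constant(axon: AxonModel, inj_current_na: float | None = None,
                    inj_position_mm: float | None = None, *, dt: float = 0.02,
                    t_end: float = 120.0, settle_ms: float = 20.0,
                    direction: str = "right") -> float:
    """Steady-state length constant (mm) from a small hyperpolarizing current.

    A steady current (default -50 nA scaled by (d/500)^1.5 to stay in the
    quasi-linear regime) is injected at the axon midpoint; after the voltage
    profile stops changing, lambda is the interpolated distance at which the
    deflection has fallen to 1/e of its value at the injection site.
    """
    if inj_position_mm is None:
        inj_position_mm = axon.length_mm / 2.0
    if inj_current_na is None:
        inj_current_na = -50.0 * (axon.diameter_um / 500.0) ** 1.5
    seg = axon.segment_at(inj_position_mm)
    stim = StimulusProtocol(segment=seg, amplitude_na=inj_current_na,
                            onset_ms=settle_ms, width_ms=1.0, steady=True)
    stride = max(int(round(1.0 / dt)), 1)
    res = axon.simulate(stim=stim, dt=dt, t_end=t_end, save_v_stride=stride)
    frames, times = res.v_field, res.t_field
    base_idx = int(np.searchsorted(times, settle_ms) - 1)
    baseline = frames[max(base_idx, 0)]
    dv_last = frames[-1] - baseline
    dv_prev = frames[-2] - baseline
    if np.max(np.abs(dv_last - dv_prev)) > 1e-3 * np.max(np.abs(dv_last)):
        raise RuntimeError("steady state not reached; increase t_end")
    return length_constant_from_profile(res.x_mm, dv_last, axon.x_mm[seg],
                                        direction=direction)


def charge_transfer(t, current, window=None):
    """Trapezoidal inward/outward charge of a current trace.

    Returns (inward, outward, ratio): inward is the integral magnitude of the
    negative part, outward of the positive part, ratio = outward/inward.
    With current in mA cm^-2 and t in ms, charges are in uC cm^-2.
    """
    t = np.asarray(t, float)
    i = np.asarray(current, float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, i = t[mask], i[mask]
    outward = float(np.trapezoid(np.clip(i, 0.0, None), t))
    inward = float(-np.trapezoid(np.clip(i, None, 0.0), t))
    ratio = outward / inward if inward > 0 else np.inf
    return inward, outward, ratio


def spike_train_stats(wave: APWaveform, detect_threshold: float = 0.0):
    """Spike times (upward threshold crossings, >= 2 ms apart) and mean rate.

    Rate (Hz) = (count - 1) / span of spike times; fewer than 2 spikes yields
    a NaN rate (flagged by the caller via the spike count).
    """
    v, t = wave.v, wave.t
    above = v >= detect_threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for idx in crossings:
        tc = float(t[idx])
        if not times or tc - times[-1] >= SPIKE_REFRACTORY_MS:
            times.append(tc)
    times = np.asarray(times)
    if times.size < 2:
        return times, float("nan")
    rate_hz = (times.size - 1) / (times[-1] - times[0]) * 1e3
    return times, float(rate_hz)
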