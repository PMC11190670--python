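"""Experiment drivers for thermal-block studies.

Temperature-step and ramp current analyses, minimum block-length and
block-temperature searches (bisection over a verified monotone bracket),
threshold-current searches, repetitive-firing block, spatial snapshots with
length-constant rescaling, and diameter-scaling sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import measure
from .cable import (AxonModel, StimulusProtocol, TemperatureField, default_dx,
                    standard_stimulus_amplitude)
from .measure import APWaveform, classify_block, length_constant, spike_train_stats
from .membrane import MembraneParams, MODIFIED, ORIGINAL

__all__ = [
    "BlockSearchSpec",
    "ScalingResult",
    "build_block_axon",
    "propagation_blocked",
    "min_block_length",
    "min_block_temperature",
    "threshold_current",
    "temperature_step_currents",
    "ramp_currents",
    "repetitive_firing_block",
    "spatial_snapshot_rescaled",
    "scaling_sweep",
]

CONTROL_T = 6.3
#: default search tolerances (length mm, temperature degC, current rel.)
LENGTH_TOL_MM = 0.01
TEMP_TOL_C = 0.05
CURRENT_RTOL = 0.01


def _velocity_guess(diameter_um: float) -> float:
    """Rough conduction velocity (m/s) used only for sizing t_end."""
    return max(11.0 * np.sqrt(diameter_um / 500.0), 0.05)


def protocol_axon_length(diameter_um: float, minimum_mm: float = 0.0) -> float:
    """Axon length (mm) used in diameter sweeps: about 20 passive length
    constants, clipped to [10, 100] mm, and at least ``minimum_mm``.

    A 100 mm axon is the standard geometry; for thin axons it is tens of
    thousands of length constants long and can be shortened without
    affecting input resistance or block behavior.
    """
    lam = default_dx(diameter_um, MODIFIED) * 40.0  # passive lambda (mm)
    return float(max(min(max(20.0 * lam, 10.0), 100.0), minimum_mm))


@dataclass
class BlockSearchSpec:
    """Settings for a minimum block-length or block-temperature search."""

    variant: str = MODIFIED
    diameter_um: float = 500.0
    flank_temp: float = CONTROL_T
    central_temp: float = 29.5
    length_bounds_mm: tuple = (0.05, 20.0)
    temp_bounds_c: tuple = (10.0, 40.0)
    central_length_mm: float | None = None      # fixed length for temp search
    length_tol_mm: float = LENGTH_TOL_MM
    temp_tol_c: float = TEMP_TOL_C
    placement: str = "centered"                 # | "midpoint" | "initial"
    axon_length_mm: float = 100.0
    stimulus_na: float | None = None            # default: diameter rule
    stimulus_width_ms: float = 1.0
    dt: float = 0.01
    params: MembraneParams | None = None
    ablation_species: str | None = None         # "Na" | "K" | "both"
    compensation: bool = False

    def __post_init__(self):
        if self.length_bounds_mm[0] >= self.length_bounds_mm[1]:
            raise ValueError("length_bounds_mm must be ordered")
        if self.temp_bounds_c[0] >= self.temp_bounds_c[1]:
            raise ValueError("temp_bounds_c must be ordered")
        if self.length_tol_mm <= 0 or self.temp_tol_c <= 0:
            raise ValueError("tolerances must be positive")
        if self.placement not in ("centered", "midpoint", "initial"):
            raise ValueError(f"unknown placement {self.placement!r}")


def build_block_axon(spec: BlockSearchSpec, central_temp: float,
                     central_length_mm: float) -> AxonModel:
    """Three-section axon with a heated central region at the requested
    placement; central segment length <= central length / 20."""
    L = spec.axon_length_mm
    if spec.placement == "centered":
        start = L / 2.0 - central_length_mm / 2.0
    elif spec.placement == "midpoint":
        start = L / 2.0
    else:
        start = 0.0
    if start < 0 or start + central_length_mm > L:
        raise ValueError("heated region does not fit in the axon")
    p = spec.params or MembraneParams(model_variant=spec.variant)
    dx_flank = default_dx(spec.diameter_um, spec.variant, spec.flank_temp, p)
    dx_center = min(dx_flank, central_length_mm / 20.0)
    sections = []
    if start > 0:
        sections.append((start, spec.flank_temp, dx_flank))
    sections.append((central_length_mm, central_temp, dx_center))
    tail = L - start - central_length_mm
    if tail > 0:
        sections.append((tail, spec.flank_temp, dx_flank))
    return AxonModel.from_sections(sections, variant=spec.variant,
                                   diameter_um=spec.diameter_um, params=p)


def _apply_condition(axon: AxonModel, spec: BlockSearchSpec, start_mm: float,
                     length_mm: float):
    """Optionally ablate channels in the heated region; returns
    (axon_to_run, clamp_record_builder or None)."""
    if spec.ablation_species is None:
        return axon, None
    from .ablation import AblationSpec, apply_ablation, build_clamp_record

    aspec = AblationSpec(start_mm=start_mm, length_mm=length_mm,
                         species=spec.ablation_species,
                         compensation=spec.compensation)
    ablated = apply_ablation(axon, aspec)
    if not spec.compensation:
        return ablated, None

    def clamp(n_steps, dt):
        return build_clamp_record(axon, aspec, n_steps=n_steps, dt=dt)

    return ablated, clamp


def propagation_blocked(spec: BlockSearchSpec, central_temp: float,
                        central_length_mm: float, *, probe_frac: float = 0.99,
                        return_result: bool = False):
    """Run one stimulated trial and classify block at the far end
    (-60 mV criterion at probe_frac of the axon length)."""
    axon = build_block_axon(spec, central_temp, central_length_mm)
    L = spec.axon_length_mm
    if spec.placement == "centered":
        start = L / 2.0 - central_length_mm / 2.0
    elif spec.placement == "midpoint":
        start = L / 2.0
    else:
        start = 0.0
    intact = axon
    axon, clamp = _apply_condition(axon, spec, start, central_length_mm)

    amp = spec.stimulus_na
    if amp is None:
        amp = standard_stimulus_amplitude(spec.diameter_um)
    onset = 5.0
    initial_state = None
    if spec.ablation_species is not None:
        # start from the intact resting profile: with compensation the clamp
        # holds it; without, the region settles toward its shifted rest
        # during a longer pre-stimulus window (the paper's settling run)
        initial_state = intact.resting_profile()
        if not spec.compensation:
            onset = 25.0
    stim = StimulusProtocol(segment=0, amplitude_na=amp,
                            width_ms=spec.stimulus_width_ms, onset_ms=onset)
    t_end = onset + 1.3 * L / _velocity_guess(spec.diameter_um) + 8.0
    n_steps = int(round(t_end / spec.dt))
    injected = clamp(n_steps, spec.dt) if clamp is not None else None
    probe_x = probe_frac * L
    res = axon.simulate(stim=stim, dt=spec.dt, t_end=t_end, probes=[probe_x],
                        injected_currents=injected, initial_state=initial_state)
    wave = APWaveform.from_result(res, probe_x)
    post = wave.t >= onset   # classify on the post-stimulus window only
    wave = APWaveform(x_mm=wave.x_mm, t=wave.t[post], v=wave.v[post],
                      v_rest=wave.v_rest)
    blocked = classify_block(wave)
    return (blocked, res) if return_result else blocked


def min_block_length(spec: BlockSearchSpec) -> float:
    """Smallest heated-region length (mm, to tolerance) that blocks the AP.

    Bisection on the central-region length after verifying the monotone
    bracket: unblocked at the lower bound, blocked at the upper bound.
    Returns the blocked upper end of the final bracket.
    """
    lo, hi = spec.length_bounds_mm
    if not propagation_blocked(spec, spec.central_temp, hi):
        raise RuntimeError(
            f"not blocked at upper bound {hi} mm: temperature "
            f"{spec.central_temp} degC below block threshold")
    if propagation_blocked(spec, spec.central_temp, lo):
        raise RuntimeError(f"already blocked at lower bound {lo} mm")
    while hi - lo > spec.length_tol_mm:
        mid = 0.5 * (lo + hi)
        if propagation_blocked(spec, spec.central_temp, mid):
            hi = mid
        else:
            lo = mid
    return hi


def min_block_temperature(spec: BlockSearchSpec) -> float:
    """Smallest central temperature (degC, to tolerance) that blocks the AP
    at the spec's fixed central length; bisection over a verified bracket."""
    if spec.central_length_mm is None:
        raise ValueError("central_length_mm must be set for temperature search")
    lo, hi = spec.temp_bounds_c
    if not propagation_blocked(spec, hi, spec.central_length_mm):
        raise RuntimeError(f"not blocked at upper temperature bound {hi} degC")
    if propagation_blocked(spec, lo, spec.central_length_mm):
        raise RuntimeError(f"already blocked at lower temperature bound {lo} degC")
    while hi - lo > spec.temp_tol_c:
        mid = 0.5 * (lo + hi)
        if propagation_blocked(spec, mid, spec.central_length_mm):
            hi = mid
        else:
            lo = mid
    return hi


def threshold_current(axon: AxonModel, pulse_width_ms: float = 0.5, *,
                      dt: float = 0.01, rtol: float = CURRENT_RTOL,
                      probe_frac: float = 0.9, bracket_na=None) -> float:
    """Minimum current amplitude (nA) whose pulse initiates a propagating AP.

    AP presence is judged at ``probe_frac`` of the axon length with the same
    -60 mV criterion used for block classification; bisection to a relative
    tolerance on the amplitude.
    """
    onset = 5.0
    L = axon.length_mm
    t_end = onset + 1.3 * L / _velocity_guess(axon.diameter_um) + 8.0
    probe_x = probe_frac * L
    if bracket_na is None:
        # brackets scale with the expected d^(3/2) law; generous on both sides
        scale = axon.diameter_um ** 1.5
        bracket_na = (0.002 * scale, 50.0 * scale)

    def fires(amp):
        stim = StimulusProtocol(segment=0, amplitude_na=amp,
                                width_ms=pulse_width_ms, onset_ms=onset)
        res = axon.simulate(stim=stim, dt=dt, t_end=t_end, probes=[probe_x])
        return not classify_block(APWaveform.from_result(res, probe_x))

    lo, hi = bracket_na
    if fires(lo):
        raise RuntimeError(f"already fires at lower bracket {lo} nA")
    # expand geometrically from lo until an AP is seen
    amp = lo
    while amp < hi:
        amp *= 2.0
        if fires(min(amp, hi)):
            hi = min(amp, hi)
            break
    else:
        raise RuntimeError(f"no AP at upper bracket {bracket_na[1]} nA")
    lo = hi / 2.0
    while (hi - lo) / hi > rtol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def temperature_step_currents(variant: str, step_temp: float, *,
                              diameter_um: float = 500.0, length_mm: float = 100.0,
                              dt: float = 0.01, params: MembraneParams | None = None):
    """Two-section axon (left half at 6.3 degC, right half at step_temp) with
    per-species currents recorded at the junction during AP passage."""
    p = params or MembraneParams(model_variant=variant)
    dx = default_dx(diameter_um, variant, CONTROL_T, p)
    mid = length_mm / 2.0
    axon = AxonModel.from_sections(
        [(mid, CONTROL_T, dx), (mid, step_temp, dx)],
        variant=variant, diameter_um=diameter_um, params=p)
    stim = StimulusProtocol(segment=0,
                            amplitude_na=standard_stimulus_amplitude(diameter_um),
                            width_ms=1.0, onset_ms=5.0)
    t_end = 5.0 + 1.4 * length_mm / _velocity_guess(diameter_um) + 10.0
    return axon.simulate(stim=stim, dt=dt, t_end=t_end,
                         probes=[mid], record_currents_at=[mid])


def ramp_currents(variant: str, *, t_hot: float = 25.0, a_mm: float = 40.0,
                  b_mm: float = 60.0, diameter_um: float = 500.0,
                  length_mm: float = 100.0, dt: float = 0.01,
                  params: MembraneParams | None = None):
    """Smooth temperature ramp from 6.3 degC (x<=a) to t_hot (x>=b) with
    per-species currents recorded at 25%, 50% and 75% of the length."""
    p = params or MembraneParams(model_variant=variant)
    field_ = TemperatureField.ramp(CONTROL_T, t_hot, a_mm, b_mm)
    axon = AxonModel.with_field(field_, variant=variant, diameter_um=diameter_um,
                                length_mm=length_mm, params=p)
    stim = StimulusProtocol(segment=0,
                            amplitude_na=standard_stimulus_amplitude(diameter_um),
                            width_ms=1.0, onset_ms=5.0)
    probes = [0.25 * length_mm, 0.5 * length_mm, 0.75 * length_mm]
    t_end = 5.0 + 1.4 * length_mm / _velocity_guess(diameter_um) + 10.0
    return axon.simulate(stim=stim, dt=dt, t_end=t_end,
                         probes=probes, record_currents_at=probes)


def repetitive_firing_block(variant: str = ORIGINAL, drive: str = "steady", *,
                            block_temp: float = 35.0,
                            block_length_mm: float | None = None,
                            block_margin: float = 1.1,
                            diameter_um: float = 500.0, length_mm: float = 100.0,
                            drive_na: float = 2000.0, pulse_period_ms: float = 15.0,
                            t_drive_ms: float = 250.0, dt: float = 0.01,
                            params: MembraneParams | None = None):
    """Drive the axon repetitively against a single-AP-blocking region.

    Returns (rate at 25% length in Hz, spike count at 90% length, result).
    If block_length_mm is None, the heated length is the minimum single-AP
    block length at block_temp times ``block_margin``: a region "sufficient
    to block a single action potential" rather than the marginal minimum,
    since exactly at threshold the block of train waveforms is marginal too.

    Defaults use the original Hodgkin/Huxley variant, whose steady-drive
    firing rate under 2000 nA is about 80 Hz; the modified variant fires
    only once under this drive (strong potassium-mediated adaptation) and
    can be selected explicitly.
    """
    spec = BlockSearchSpec(variant=variant, diameter_um=diameter_um,
                           central_temp=block_temp, axon_length_mm=length_mm,
                           dt=dt, params=params)
    if block_length_mm is None:
        block_length_mm = block_margin * min_block_length(spec)
    axon = build_block_axon(spec, block_temp, block_length_mm)
    onset = 10.0
    if drive == "steady":
        stim = StimulusProtocol(segment=0, amplitude_na=drive_na,
                                onset_ms=onset, width_ms=1.0, steady=True)
    elif drive == "pulse-train":
        stim = StimulusProtocol(segment=0, amplitude_na=drive_na,
                                onset_ms=onset, width_ms=1.0,
                                period_ms=pulse_period_ms)
    else:
        raise ValueError(f"unknown drive {drive!r}")
    probes = [0.25 * length_mm, 0.9 * length_mm]
    res = axon.simulate(stim=stim, dt=dt, t_end=onset + t_drive_ms,
                        probes=probes)
    _, rate = spike_train_stats(APWaveform.from_result(res, probes[0]))
    far_spikes, _ = spike_train_stats(APWaveform.from_result(res, probes[1]))
    return rate, len(far_spikes), res


def spatial_snapshot_rescaled(variant: str = MODIFIED, diameter_um: float = 500.0,
                              *, block: bool = True, block_temp: float = 29.5,
                              block_length_mm: float | None = None,
                              length_mm: float = 100.0, dt: float = 0.01,
                              params: MembraneParams | None = None,
                              lambda_mm: float | None = None) -> dict:
    """Voltage along the whole axon at the instant the control AP peak
    reaches the midpoint, raw and rescaled by the length constant.

    The block case heats the minimum-block-length region starting at the
    midpoint (the Fig.-6 style placement) and records at the identical time
    after the stimulus.
    """
    p = params or MembraneParams(model_variant=variant)
    mid = length_mm / 2.0
    amp = standard_stimulus_amplitude(diameter_um)
    stim = StimulusProtocol(segment=0, amplitude_na=amp, width_ms=1.0, onset_ms=5.0)
    t_end = 5.0 + 1.2 * mid / _velocity_guess(diameter_um) + 6.0

    control = AxonModel.uniform(CONTROL_T, variant=variant,
                                diameter_um=diameter_um, length_mm=length_mm,
                                params=p)
    res_c = control.simulate(stim=stim, dt=dt, t_end=t_end, probes=[mid],
                             save_v_stride=2)
    w = res_c.probe(mid)
    t_peak = res_c.t[int(np.argmax(w))]
    frame = int(np.argmin(np.abs(res_c.t_field - t_peak)))
    out = {
        "x_mm": res_c.x_mm,
        "t_snapshot_ms": float(res_c.t_field[frame]),
        "v_control": res_c.v_field[frame],
    }

    if lambda_mm is None:
        lambda_mm = length_constant(control)
    out["lambda_mm"] = float(lambda_mm)
    out["xi"] = (res_c.x_mm - mid) / lambda_mm

    if block:
        spec = BlockSearchSpec(variant=variant, diameter_um=diameter_um,
                               central_temp=block_temp, placement="midpoint",
                               axon_length_mm=length_mm, dt=dt, params=p)
        if block_length_mm is None:
            block_length_mm = min_block_length(spec)
        out["block_length_mm"] = float(block_length_mm)
        axon_b = build_block_axon(spec, block_temp, block_length_mm)
        res_b = axon_b.simulate(stim=stim, dt=dt, t_end=t_end, probes=[mid],
                                save_v_stride=2)
        frame_b = int(np.argmin(np.abs(res_b.t_field - out["t_snapshot_ms"])))
        # the blocked axon has its own (finer) grid; interpolate onto control x
        out["v_block"] = np.interp(res_c.x_mm, res_b.x_mm, res_b.v_field[frame_b])
    return out


@dataclass
class ScalingResult:
    """Per-diameter outcomes with a least-squares scaling fit."""

    kind: str
    diameters_um: np.ndarray
    values: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    loglog_slope: float | None = None
    failed: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"scaling sweep: {self.kind}",
                 f"{'d (um)':>10} {'value':>12}"]
        for d, v in zip(self.diameters_um, self.values):
            lines.append(f"{d:>10.1f} {v:>12.5g}")
        lines.append(f"linear fit vs predictor: slope={self.slope:.5g} "
                     f"intercept={self.intercept:.5g} R^2={self.r_squared:.4f}")
        if self.loglog_slope is not None:
            lines.append(f"log-log slope vs diameter: {self.loglog_slope:.3f}")
        return "\n".join(lines)


def _linear_fit(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def scaling_sweep(kind: str, diameters_um, variant: str = ORIGINAL, *,
                  central_temp: float = 35.0, pulse_width_ms: float = 0.5,
                  initial_region_mm: float = 10.0, temp_bounds=(6.5, 45.0),
                  threshold_currents: dict | None = None,
                  dt: float = 0.01, params: MembraneParams | None = None) -> ScalingResult:
    """Sweep diameters and fit the observable against its predicted scaling.

    kind = "block-length": minimum block length at central_temp vs sqrt(d).
    kind = "block-temperature": minimum initiation-block temperature (heated
    initial region containing the stimulus site) vs sqrt(d); each diameter is
    stimulated at its threshold current (given or searched).
    kind = "threshold-current": minimum initiating current vs d^(3/2); also
    reports the log-log slope against diameter.
    """
    diameters = np.asarray(sorted(diameters_um), float)
    if diameters.size < 3:
        raise ValueError("need at least 3 diameters for a scaling fit")
    values = np.full(diameters.size, np.nan)
    failed = {}
    for i, d in enumerate(diameters):
        try:
            if kind == "block-length":
                L = protocol_axon_length(d)
                spec = BlockSearchSpec(
                    variant=variant, diameter_um=d, central_temp=central_temp,
                    axon_length_mm=L, dt=dt, params=params,
                    length_bounds_mm=(0.001 * L, 0.35 * L))
                values[i] = min_block_length(spec)
            elif kind == "threshold-current":
                L = protocol_axon_length(d)
                axon = AxonModel.uniform(CONTROL_T, variant=variant,
                                         diameter_um=d, length_mm=L,
                                         params=params)
                values[i] = threshold_current(axon, pulse_width_ms, dt=dt)
            elif kind == "block-temperature":
                L = protocol_axon_length(d, minimum_mm=3.0 * initial_region_mm)
                if threshold_currents and d in threshold_currents:
                    amp = threshold_currents[d]
                else:
                    axon = AxonModel.uniform(CONTROL_T, variant=variant,
                                             diameter_um=d, length_mm=L,
                                             params=params)
                    amp = threshold_current(axon, pulse_width_ms, dt=dt)
                spec = BlockSearchSpec(
                    variant=variant, diameter_um=d, placement="initial",
                    central_length_mm=initial_region_mm, axon_length_mm=L,
                    temp_bounds_c=temp_bounds, stimulus_na=amp,
                    stimulus_width_ms=pulse_width_ms, dt=dt, params=params)
                values[i] = min_block_temperature(spec)
            else:
                raise ValueError(f"unknown sweep kind {kind!r}")
        except RuntimeError as exc:
            failed[float(d)] = str(exc)

    ok = np.isfinite(values)
    if ok.sum() < 3:
        raise RuntimeError(f"too few successful diameters: failures {failed}")
    if kind == "threshold-current":
        predictor = diameters[ok] ** 1.5
    else:
        predictor = np.sqrt(diameters[ok])
    slope, intercept, r2 = _linear_fit(predictor, values[ok])
    loglog = None
    if kind == "threshold-current":
        loglog = float(np.polyfit(np.log(diameters[ok]), np.log(values[ok]), 1)[0])
    return ScalingResult(kind=kind, diameters_um=diameters[ok], values=values[ok],
                         slope=slope, intercept=intercept, r_squared=r2,
                         loglog_slope=loglog, failed=failed)
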