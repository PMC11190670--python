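"""Region-wise channel ablation and the compensatory-current (dynamic-clamp)
paired-simulation procedure.

Ablation zeroes the voltage-gated conductances of one or both species inside
a region, emulating TTX (sodium) or TEA (potassium) application. Because the
voltage-gated channels contribute to the resting potential, ablation shifts
the region's rest; the compensatory clamp removes that confound by recording
the ablated species' ionic current from an intact reference axon held at
rest and injecting its negative into the ablated region (record-then-replay,
two passes on identical grids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable import AxonModel, SimulationResult, StimulusProtocol

__all__ = [
    "AblationSpec",
    "apply_ablation",
    "build_clamp_record",
    "compensatory_clamp",
    "clamp_fidelity_mse",
    "ablation_block_table",
]

SPECIES = ("Na", "K", "both")


@dataclass(frozen=True)
class AblationSpec:
    """Channel removal over [start, start+length) mm."""

    start_mm: float
    length_mm: float
    species: str = "both"
    compensation: bool = False

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")


def apply_ablation(axon: AxonModel, spec: AblationSpec) -> AxonModel:
    """Copy of the axon with the spec's voltage-gated conductances zeroed
    inside the region; everything else untouched."""
    mask = axon.region_mask(spec.start_mm, spec.length_mm)
    gk = 0.0 if spec.species in ("K", "both") else None
    gna = 0.0 if spec.species in ("Na", "both") else None
    return axon.with_conductance_scale(mask, gk_scale=gk, gna_scale=gna)


def build_clamp_record(reference: AxonModel, spec: AblationSpec, *,
                       n_steps: int, dt: float,
                       stim: StimulusProtocol | None = None) -> dict:
    """Pass 1 of the clamp: simulate the intact reference axon and record
    the ablated species' ionic current in the region.

    The reference runs unstimulated (at rest) by default, so the record is
    the current the missing channels would carry at the control resting
    potential; ``stim`` optionally replays a stimulated reference instead.
    Returns {segment: -I(t) in nA} ready to inject into the ablated axon.
    """
    mask = reference.region_mask(spec.start_mm, spec.length_mm)
    res = reference.simulate(stim=stim, dt=dt, t_end=n_steps * dt,
                             record_species=(spec.species, mask))
    segs = res.species_segments
    total = np.zeros((n_steps, segs.size))
    for arr in res.species_record.values():
        total += arr
    area = reference.area_cm2[segs]
    inject_na = -total * area * 1e6       # mA/cm^2 * cm^2 -> mA; *1e6 -> nA
    return {int(j): inject_na[:, k] for k, j in enumerate(segs)}


def compensatory_clamp(reference: AxonModel, ablated: AxonModel,
                       spec: AblationSpec, stim: StimulusProtocol | None, *,
                       dt: float = 2e-4, t_end: float = 50.0,
                       stimulate_reference: bool = False,
                       **sim_kw) -> SimulationResult:
    """Two-pass dynamic clamp: record from the intact reference, replay the
    negated record into the ablated axon while running the protocol stimulus.

    Reference and ablated axons must share the spatial grid and the time
    grid exactly (grid mismatch raises); with no stimulus the clamped
    region's potential stays at the control resting potential.
    """
    if reference.n_seg != ablated.n_seg or not np.allclose(
            reference.seg_len_mm, ablated.seg_len_mm):
        raise ValueError("reference and ablated axons have mismatched grids")
    if not np.allclose(reference.seg_temp, ablated.seg_temp):
        raise ValueError("reference and ablated axons have mismatched temperatures")
    n_steps = int(round(t_end / dt))
    record = build_clamp_record(reference, spec, n_steps=n_steps, dt=dt,
                                stim=stim if stimulate_reference else None)
    # the clamp holds the region at the *control* rest: start there
    v0, g0 = reference.resting_profile()
    return ablated.simulate(stim=stim, dt=dt, t_end=t_end,
                            injected_currents=record,
                            initial_state=(v0, g0), **sim_kw)


def clamp_fidelity_mse(control: SimulationResult,
                       clamped: SimulationResult) -> float:
    """Mean over segments of the squared difference in per-segment peak
    voltage change (max over time minus rest), in mV^2."""
    if control.x_mm.shape != clamped.x_mm.shape or not np.allclose(
            control.x_mm, clamped.x_mm):
        raise ValueError("results are on different spatial grids")
    peak_c = control.vmax - control.v_rest
    peak_x = clamped.vmax - clamped.v_rest
    return float(np.mean((peak_c - peak_x) ** 2))


def ablation_block_table(variant: str, temperatures, *,
                         conditions=("intact", "both", "Na", "K"),
                         compensation: bool = True, diameter_um: float = 500.0,
                         axon_length_mm: float = 100.0,
                         length_bounds_mm=(0.05, 25.0), dt: float = 0.01,
                         params=None) -> dict:
    """Minimum block length per (temperature, channel condition).

    Conditions name the *ablated* species ("Na" removes sodium channels,
    leaving a potassium-only membrane, etc.); "intact" leaves all channels.
    Conditions that never block within the length bounds map to None.
    """
    from .protocols import BlockSearchSpec, min_block_length

    table = {}
    for cond in conditions:
        for temp in np.atleast_1d(temperatures):
            spec = BlockSearchSpec(
                variant=variant, diameter_um=diameter_um, central_temp=float(temp),
                axon_length_mm=axon_length_mm, length_bounds_mm=length_bounds_mm,
                dt=dt, params=params,
                ablation_species=None if cond == "intact" else cond,
                compensation=compensation and cond != "intact")
            try:
                table[(cond, float(temp))] = min_block_length(spec)
            except RuntimeError:
                table[(cond, float(temp))] = None
    return table
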