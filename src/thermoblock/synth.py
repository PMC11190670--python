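"""Synthetic "experimental" reference tables and small test axons.

The generator simulates the forward model at each temperature with a known
parameter set, measures rates of rise/fall, AP amplitude and (optionally)
conduction velocity with the same protocols calibration uses, and adds
seeded relative Gaussian noise with symmetric error bars. It stands in for
digitized squid measurements, giving every calibration stage a testable
ground truth: with zero noise, calibration must recover the generating
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import membrane as mb
from .calibrate import (CableProtocol, ReferenceTable, REFERENCE_TEMPS,
                        measure_rates)
from .cable import AxonModel, StimulusProtocol, standard_stimulus_amplitude
from .membrane import MembraneParams, MODIFIED

__all__ = ["SynthSpec", "generate_reference", "make_fixture_axons"]


@dataclass(frozen=True)
class SynthSpec:
    """Settings for synthetic reference generation.

    noise_sd is the relative standard deviation applied independently per
    quantity and temperature; error bars span +- bar_width_sd * noise_sd
    around the (noisy) mean. The seed is recorded in the output.
    """

    params: MembraneParams = field(default_factory=MembraneParams)
    temperatures: tuple = REFERENCE_TEMPS
    noise_sd: float = 0.05
    bar_width_sd: float = 1.0
    seed: int = 0
    include_velocity: bool = False
    velocity_length_mm: float = 40.0
    protocol: CableProtocol = field(default_factory=CableProtocol)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _velocity(spec: SynthSpec, temperature: float) -> float:
    from .measure import conduction_velocity

    L = spec.velocity_length_mm
    axon = AxonModel.uniform(temperature, variant=spec.params.model_variant,
                             diameter_um=500.0, length_mm=L, params=spec.params)
    stim = StimulusProtocol(segment=0, amplitude_na=20000.0,
                            width_ms=1.0, onset_ms=5.0)
    res = axon.simulate(stim=stim, dt=0.01, t_end=min(5.0 + L + 5.0, 60.0),
                        probes=[L / 2 - 8.0, L / 2 + 8.0])
    return conduction_velocity(res, L / 2 - 8.0, L / 2 + 8.0)


def generate_reference(spec: SynthSpec) -> ReferenceTable:
    """Simulate, measure, perturb: emit a ReferenceTable.

    Rows where the generating parameters fail to spike are flagged
    (ap_generated=False) with NaN rates rather than dropped. With
    noise_sd=0 the means equal the noise-free model measurements exactly,
    and a fixed seed reproduces the table bitwise.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.temperatures:
        meas = measure_rates(float(t), spec.params, spec.protocol)
        row = {"temperature_c": float(t), "seed": spec.seed,
               "ap_generated": bool(meas["spike"])}
        if not meas["spike"]:
            for c in ("rise", "rise_lower", "rise_upper", "fall",
                      "fall_lower", "fall_upper", "amplitude", "velocity"):
                row[c] = np.nan
            rows.append(row)
            continue
        truths = {"rise": meas["rise"], "fall": -meas["fall"],
                  "amplitude": meas["amplitude"]}
        if spec.include_velocity:
            truths["velocity"] = _velocity(spec, float(t))
        else:
            row["velocity"] = np.nan
        for name, truth in truths.items():
            noisy = truth * (1.0 + spec.noise_sd * rng.standard_normal())
            half = spec.bar_width_sd * spec.noise_sd * abs(truth)
            row[name] = noisy
            if name in ("rise", "fall"):
                row[f"{name}_lower"] = noisy - half
                row[f"{name}_upper"] = noisy + half
        rows.append(row)
    return ReferenceTable(pd.DataFrame(rows))


def make_fixture_axons(dx_mm: float = 0.25) -> dict:
    """Catalog of short axons (coarse grids) for fast end-to-end tests."""
    from .ablation import AblationSpec, apply_ablation

    axons = {}
    axons["uniform_6p3"] = AxonModel.uniform(
        6.3, variant=MODIFIED, diameter_um=500.0, length_mm=20.0, dx_mm=dx_mm)
    axons["uniform_original"] = AxonModel.uniform(
        6.3, variant="original_HH", diameter_um=500.0, length_mm=20.0, dx_mm=dx_mm)
    axons["two_section_step"] = AxonModel.from_sections(
        [(10.0, 6.3, dx_mm), (10.0, 15.0, dx_mm)],
        variant=MODIFIED, diameter_um=500.0)
    axons["three_section_block"] = AxonModel.from_sections(
        [(7.5, 6.3, dx_mm), (5.0, 40.0, dx_mm / 2), (7.5, 6.3, dx_mm)],
        variant=MODIFIED, diameter_um=500.0)
    spec = AblationSpec(start_mm=8.0, length_mm=4.0, species="both")
    axons["ablated_both"] = apply_ablation(axons["uniform_6p3"], spec)
    axons["ablated_na"] = apply_ablation(
        axons["uniform_6p3"], AblationSpec(8.0, 4.0, species="Na"))
    axons["ablated_k"] = apply_ablation(
        axons["uniform_6p3"], AblationSpec(8.0, 4.0, species="K"))
    return axons
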