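"""One-dimensional cable solver for an unmyelinated axon with per-segment
temperature, axial resistance and channel parameters.

The axon is discretized into cylindrical segments (sealed ends). Per time
step the gates are advanced by the exact exponential update at frozen
voltage, then the voltage is advanced implicitly (theta-method, default
backward Euler) through a tridiagonal solve, which is unconditionally stable
at the default time step of 0.01 ms.

Positions are mm from the left end; segment j occupies [sum(dx[:j]),
sum(dx[:j+1])) on that axis and is represented by its center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import membrane as mb
from .membrane import MembraneParams, GatingState, MODIFIED, ORIGINAL

__all__ = [
    "AxonGeometry",
    "TemperatureField",
    "StimulusProtocol",
    "AxialResistances",
    "AxonModel",
    "SimulationResult",
    "axial_resistivity",
    "smooth_profile",
    "segment_current",
    "build_axial_resistances",
    "default_dx",
    "run_simulation",
]

#: nA injected by the standard stimulus for thick vs thin axons
STANDARD_STIM_THICK = 2000.0
STANDARD_STIM_THIN = 100.0


def standard_stimulus_amplitude(diameter_um: float) -> float:
    """Paper convention: 2000 nA for d >= 10 um, 100 nA below."""
    return STANDARD_STIM_THICK if diameter_um >= 10.0 else STANDARD_STIM_THIN


def axial_resistivity(temperature, variant: str = MODIFIED,
                      params: MembraneParams | None = None):
    """Axial resistivity Ra in ohm cm.

    Modified variant: Ra(T) = 56.84 exp(-0.03 T), monotonically decreasing.
    Original variant: the fixed Hodgkin/Huxley value 35.4 ohm cm.
    """
    p = params if params is not None else MembraneParams(model_variant=variant)
    t = np.asarray(temperature, dtype=float)
    if variant == ORIGINAL:
        out = np.full_like(t, p.ra_fixed)
        return out if t.ndim else p.ra_fixed
    out = p.ra_coeff * np.exp(-p.ra_decay * t)
    return out if t.ndim else float(out)


def smooth_profile(x, a, b, t1, t2):
    """Piecewise-quadratic temperature ramp T(x) between t1 (x<=a) and t2 (x>=b).

    The blending function is 0 for x<=a, 2((x-a)/(b-a))^2 up to the midpoint,
    1-2((x-b)/(b-a))^2 from the midpoint to b, and 1 beyond; continuous,
    monotone, and exactly (t1+t2)/2 at (a+b)/2.
    """
    if not a < b:
        raise ValueError("smooth_profile requires a < b")
    x = np.asarray(x, dtype=float)
    s = (x - a) / (b - a)
    f = np.where(
        x <= a, 0.0,
        np.where(
            x <= (a + b) / 2.0, 2.0 * s ** 2,
            np.where(x <= b, 1.0 - 2.0 * ((x - b) / (b - a)) ** 2, 1.0),
        ),
    )
    out = t1 + (t2 - t1) * f
    return out if x.ndim else float(out)


class TemperatureField:
    """Temperature as a function of position along the axon (degC vs mm)."""

    def __init__(self, func):
        self._func = func

    def at(self, x_mm):
        return np.asarray(self._func(np.asarray(x_mm, dtype=float)), dtype=float)

    @classmethod
    def uniform(cls, temperature):
        return cls(lambda x: np.full_like(x, float(temperature)))

    @classmethod
    def two_section(cls, t_left, t_right, boundary_mm):
        return cls(lambda x: np.where(x < boundary_mm, float(t_left), float(t_right)))

    @classmethod
    def three_section(cls, t_flank, t_center, center_start_mm, center_length_mm):
        lo, hi = center_start_mm, center_start_mm + center_length_mm

        def f(x):
            return np.where((x >= lo) & (x < hi), float(t_center), float(t_flank))

        return cls(f)

    @classmethod
    def ramp(cls, t1, t2, a_mm, b_mm):
        return cls(lambda x: smooth_profile(x, a_mm, b_mm, t1, t2))


@dataclass(frozen=True)
class AxonGeometry:
    """Axon cylinder: length (mm), diameter (um) and section boundaries (mm)."""

    length_mm: float = 100.0
    diameter_um: float = 500.0
    boundaries_mm: tuple = ()

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        b = tuple(self.boundaries_mm)
        if list(b) != sorted(b) or any(not 0 < v < self.length_mm for v in b):
            raise ValueError("boundaries_mm must be sorted and inside (0, length)")


@dataclass
class StimulusProtocol:
    """Current injection into one segment.

    amplitude nA; single pulse (onset, width), periodic train (period_ms) or
    steady step (steady=True, on from onset until t_end).
    """

    segment: int = 0
    amplitude_na: float = STANDARD_STIM_THICK
    width_ms: float = 1.0
    onset_ms: float = 5.0
    period_ms: float | None = None
    steady: bool = False

    def __post_init__(self):
        if not np.isfinite(self.amplitude_na):
            raise ValueError("amplitude_na must be finite")
        if not self.steady and self.width_ms <= 0:
            raise ValueError("width_ms must be positive for pulse stimuli")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Injected current (nA) evaluated on a time grid."""
        if self.steady:
            on = t >= self.onset_ms
        elif self.period_ms:
            tt = t - self.onset_ms
            on = (tt >= 0) & (np.mod(tt, self.period_ms) < self.width_ms)
        else:
            on = (t >= self.onset_ms) & (t < self.onset_ms + self.width_ms)
        return np.where(on, self.amplitude_na, 0.0)


@dataclass
class AxialResistances:
    """Inter-segment axial resistances ra(j, j+1) in Mohm."""

    ra_mohm: np.ndarray

    def __post_init__(self):
        if np.any(self.ra_mohm <= 0):
            raise ValueError("axial resistances must be positive")


def build_axial_resistances(seg_len_mm, ra_ohm_cm, diameter_um) -> AxialResistances:
    """Series half-segment resistances between adjacent segment centers.

    ra(j,j+1) = [Ra_j Lj/2 + Ra_{j+1} L_{j+1}/2] / (pi r^2), converted to Mohm.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    seg_len_cm = np.asarray(seg_len_mm, dtype=float) / 10.0
    ra = np.asarray(ra_ohm_cm, dtype=float)
    r_cm = diameter_um / 1e4 / 2.0
    area = np.pi * r_cm ** 2
    half = ra * seg_len_cm / 2.0 / area          # ohm per half segment
    ra_ohm = half[:-1] + half[1:]
    return AxialResistances(ra_mohm=ra_ohm / 1e6)


def segment_current(v_prev, v_j, v_next, ra_left_mohm, ra_right_mohm):
    """Net axial current (nA) into segment j; pass None for a sealed end."""
    i = 0.0
    if v_prev is not None:
        i += (v_prev - v_j) / ra_left_mohm
    if v_next is not None:
        i -= (v_j - v_next) / ra_right_mohm
    return i


def default_dx(diameter_um, variant=MODIFIED, temperature=6.3,
               params: MembraneParams | None = None, per_lambda=40):
    """Default segment length (mm): passive length constant / per_lambda.

    lambda_passive = sqrt(r / (2 Ra(T) gL)); >= 40 segments per length
    constant keeps spatial discretization error well below the measurement
    tolerances used in the protocols.
    """
    p = params if params is not None else MembraneParams(model_variant=variant)
    r_cm = diameter_um / 1e4 / 2.0
    ra = axial_resistivity(temperature, variant, p)
    lam_cm = np.sqrt(r_cm / (2.0 * ra * p.g_leak))
    return float(lam_cm * 10.0 / per_lambda)


@dataclass
class SimulationResult:
    """Time/space voltage records plus optional per-probe current densities."""

    t: np.ndarray                       # ms, (n_t,)
    x_mm: np.ndarray                    # segment centers, (n_seg,)
    probe_v: dict                       # x_mm -> V(t) (mV)
    probe_currents: dict                # x_mm -> CurrentBreakdown of arrays
    vmax: np.ndarray                    # per-segment max over time (mV)
    v_rest: np.ndarray                  # per-segment initial rest (mV)
    v_field: np.ndarray | None = None   # (n_saved, n_seg) if requested
    t_field: np.ndarray | None = None   # times of saved frames
    injected_charge_nc: float = 0.0     # total injected charge (nC)
    membrane_charge_nc: float = 0.0     # integrated ionic + capacitive (nC)
    metadata: dict = field(default_factory=dict)
    species_record: dict | None = None  # species -> (n_steps, n_masked) mA/cm^2
    species_segments: np.ndarray | None = None

    def probe(self, x_mm: float) -> np.ndarray:
        """Voltage trace at the probe closest to x_mm."""
        key = min(self.probe_v, key=lambda p: abs(p - x_mm))
        return self.probe_v[key]

    def plot(self, ax=None, **kw):  # pragma: no cover - optional plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for x, v in sorted(self.probe_v.items()):
            ax.plot(self.t, v, label=f"x = {x:.1f} mm", **kw)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("membrane potential (mV)")
        ax.legend()
        return ax


class AxonModel:
    """Discretized axon: geometry + per-segment temperature and parameters.

    The single source of truth for a simulation. Per-segment conductance
    scale factors implement channel ablation; a ``MembraneParams`` override
    per instance implements Q10 neutralization and similar variants.
    """

    def __init__(self, variant, diameter_um, seg_len_mm, seg_temp,
                 params: MembraneParams | None = None,
                 gk_scale=None, gna_scale=None, check_temperature=True,
                 ra_override=None):
        seg_len_mm = np.asarray(seg_len_mm, dtype=float)
        seg_temp = np.asarray(seg_temp, dtype=float)
        if seg_len_mm.ndim != 1 or seg_len_mm.size < 1:
            raise ValueError("seg_len_mm must be a 1-d array")
        if seg_temp.shape != seg_len_mm.shape:
            raise ValueError("seg_temp must match seg_len_mm")
        if np.any(seg_len_mm <= 0):
            raise ValueError("segment lengths must be positive")
        if params is None:
            params = MembraneParams(model_variant=variant)
        elif params.model_variant != variant:
            raise ValueError("params.model_variant disagrees with variant")
        if check_temperature and variant == MODIFIED:
            tmin, tmax = seg_temp.min(), seg_temp.max()
            if tmin < 5.0 - 1e-9 or tmax > 40.0 + 1e-9:
                raise ValueError(
                    f"temperatures [{tmin:.2f}, {tmax:.2f}] outside model "
                    "validity range 5-40 degC")
            if tmax > 25.0 + 1e-9:
                warnings.warn(
                    "temperatures above 25 degC extrapolate the fitted Q10 "
                    "intervals", stacklevel=2)

        self.variant = variant
        self.diameter_um = float(diameter_um)
        self.params = params
        self.seg_len_mm = seg_len_mm
        self.seg_temp = seg_temp
        n = seg_len_mm.size
        self.gk_scale = np.ones(n) if gk_scale is None else np.asarray(gk_scale, float)
        self.gna_scale = np.ones(n) if gna_scale is None else np.asarray(gna_scale, float)
        if self.gk_scale.shape != (n,) or self.gna_scale.shape != (n,):
            raise ValueError("conductance scale arrays must be per-segment")

        edges = np.concatenate(([0.0], np.cumsum(seg_len_mm)))
        self.x_mm = 0.5 * (edges[:-1] + edges[1:])
        self.length_mm = float(edges[-1])
        d_cm = self.diameter_um / 1e4
        self.area_cm2 = np.pi * d_cm * (seg_len_mm / 10.0)     # lateral area
        self.ra_override = ra_override
        if ra_override is not None:
            self.ra_per_seg = np.full(n, float(ra_override))
        else:
            self.ra_per_seg = np.asarray(
                axial_resistivity(seg_temp, variant, params), dtype=float)
        self.axial = build_axial_resistances(seg_len_mm, self.ra_per_seg, diameter_um)

        # temperature-dependent per-segment membrane coefficients
        self.phi_m = np.asarray(mb.phi(seg_temp, "m", params), float)
        self.phi_h = np.asarray(mb.phi(seg_temp, "h", params), float)
        self.phi_n = np.asarray(mb.phi(seg_temp, "n", params), float)
        g_k, g_na = mb.peak_conductances(seg_temp, params)
        self.g_k = np.asarray(g_k, float) * self.gk_scale
        self.g_na = np.asarray(g_na, float) * self.gna_scale
        self.g_pump = np.asarray(mb.pump_conductance(seg_temp, params), float)
        self._rest_cache = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def uniform(cls, temperature, *, variant=MODIFIED, diameter_um=500.0,
                length_mm=100.0, dx_mm=None, params=None, ra_override=None):
        if dx_mm is None:
            dx_mm = default_dx(diameter_um, variant,
                               params=params or MembraneParams(model_variant=variant))
        n = max(int(round(length_mm / dx_mm)), 3)
        seg_len = np.full(n, length_mm / n)
        return cls(variant, diameter_um, seg_len, np.full(n, float(temperature)),
                   params=params, ra_override=ra_override)

    @classmethod
    def from_sections(cls, sections, *, variant=MODIFIED, diameter_um=500.0,
                      params=None):
        """Build from [(length_mm, temperature, dx_mm), ...] sections."""
        lens, temps = [], []
        for length_mm, temperature, dx_mm in sections:
            n = max(int(round(length_mm / dx_mm)), 1)
            lens.append(np.full(n, length_mm / n))
            temps.append(np.full(n, float(temperature)))
        return cls(variant, diameter_um, np.concatenate(lens),
                   np.concatenate(temps), params=params)

    @classmethod
    def with_field(cls, temperature_field: TemperatureField, *, variant=MODIFIED,
                   diameter_um=500.0, length_mm=100.0, dx_mm=None, params=None):
        if dx_mm is None:
            dx_mm = default_dx(diameter_um, variant,
                               params=params or MembraneParams(model_variant=variant))
        n = max(int(round(length_mm / dx_mm)), 3)
        seg_len = np.full(n, length_mm / n)
        edges = np.concatenate(([0.0], np.cumsum(seg_len)))
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(variant, diameter_um, seg_len,
                   temperature_field.at(centers), params=params)

    # -- derived state --------------------------------------------------------

    @property
    def n_seg(self) -> int:
        return self.seg_len_mm.size

    def segment_at(self, x_mm: float) -> int:
        edges = np.concatenate(([0.0], np.cumsum(self.seg_len_mm)))
        idx = int(np.searchsorted(edges, x_mm, side="right") - 1)
        return min(max(idx, 0), self.n_seg - 1)

    def region_mask(self, start_mm: float, length_mm: float) -> np.ndarray:
        """Segments whose centers fall in [start, start+length)."""
        if start_mm < -1e-9 or start_mm + length_mm > self.length_mm + 1e-9:
            raise ValueError("region outside axon")
        return (self.x_mm >= start_mm) & (self.x_mm < start_mm + length_mm)

    def with_conductance_scale(self, mask, gk_scale=None, gna_scale=None):
        """Copy of the axon with voltage-gated conductances rescaled on mask."""
        gk = self.gk_scale.copy()
        gna = self.gna_scale.copy()
        if gk_scale is not None:
            gk[mask] = gk_scale
        if gna_scale is not None:
            gna[mask] = gna_scale
        return AxonModel(self.variant, self.diameter_um, self.seg_len_mm,
                         self.seg_temp, params=self.params,
                         gk_scale=gk, gna_scale=gna, check_temperature=False,
                         ra_override=self.ra_override)

    def resting_profile(self):
        """Per-segment resting potential and gates from local root-finding.

        Segments sharing (temperature, ablation scales) share one root-find.
        Axial coupling between regions of different rest relaxes during the
        pre-stimulus window of a simulation.
        """
        if self._rest_cache is not None:
            return self._rest_cache
        keys = np.stack([self.seg_temp, self.gk_scale, self.gna_scale])
        uniq, inverse = np.unique(keys.T, axis=0, return_inverse=True)
        v = np.empty(len(uniq))
        for i, (t, gk, gna) in enumerate(uniq):
            v[i], _ = mb.resting_state(t, self.params, gk_scale=gk, gna_scale=gna)
        v_rest = v[inverse]
        gates = mb.steady_state_gates(v_rest)
        self._rest_cache = (v_rest, gates)
        return self._rest_cache

    # -- simulation ------------------------------------------------------------

    def simulate(self, stim: StimulusProtocol | None = None, *, dt=0.01,
                 t_end=50.0, probes=(), record_currents_at=(),
                 injected_currents=None, save_v_stride=0, theta=1.0,
                 initial_state=None, record_species=None) -> SimulationResult:
        """Integrate the cable equation.

        Parameters
        ----------
        stim : StimulusProtocol or None
            Current injection; None runs the axon unstimulated.
        dt, t_end : float
            Time step and duration (ms).
        probes : sequence of positions (mm)
            Record full-rate voltage traces at these segments.
        record_currents_at : sequence of positions (mm)
            Additionally record per-species current densities.
        injected_currents : dict[int, ndarray] or None
            Extra per-segment current series (nA), one value per step,
            e.g. a compensatory-clamp record. Length must be n_steps.
        save_v_stride : int
            If > 0, save the full V field every this many steps.
        theta : float
            Implicitness of the voltage update (1 = backward Euler,
            0.5 = Crank-Nicolson).
        initial_state : (v, GatingState) or None
            Start from this state instead of the local resting profile.
        record_species : (species, mask) or None
            Record the named voltage-gated species current ("Na", "K" or
            "both") as a density time series for every segment in the boolean
            mask; used by the compensatory-clamp procedure. One value per
            step, evaluated at the end-of-step state.
        """
        n = self.n_seg
        n_steps = int(round(t_end / dt))
        t = np.arange(n_steps + 1) * dt

        if initial_state is None:
            v_rest, gates0 = self.resting_profile()
            v = v_rest.copy()
            m = np.asarray(gates0.m, float).copy()
            h = np.asarray(gates0.h, float).copy()
            ngate = np.asarray(gates0.n, float).copy()
        else:
            v0, g0 = initial_state
            v = np.array(v0, float, copy=True)
            m = np.array(g0.m, float, copy=True)
            h = np.array(g0.h, float, copy=True)
            ngate = np.array(g0.n, float, copy=True)
        v_rest_out = v.copy()

        stim_series = stim.waveform(t[:-1]) if stim is not None else None
        stim_seg = stim.segment if stim is not None else -1

        inj_segs, inj_vals = [], []
        if injected_currents:
            for seg, series in injected_currents.items():
                series = np.asarray(series, float)
                if series.shape != (n_steps,):
                    raise ValueError(
                        f"injected current for segment {seg} has length "
                        f"{series.size}, expected {n_steps} (grid mismatch)")
                inj_segs.append(int(seg))
                inj_vals.append(series)
        inj_segs = np.asarray(inj_segs, dtype=int)

        inv_ra = 1.0 / self.axial.ra_mohm                 # uS between centers
        inv_l = np.concatenate(([0.0], inv_ra))           # left neighbor
        inv_r = np.concatenate((inv_ra, [0.0]))           # right neighbor
        c_over_dt = self.params.c_m * self.area_cm2 * 1e3 / dt   # nA ms/mV / ms

        ab = np.zeros((3, n))
        ab[0, 1:] = -theta * inv_ra
        ab[2, :-1] = -theta * inv_ra

        probe_idx = {float(p): self.segment_at(p) for p in probes}
        cur_idx = {float(p): self.segment_at(p) for p in record_currents_at}
        probe_tr = {p: np.empty(n_steps + 1) for p in probe_idx}
        cur_tr = {p: {k: np.empty(n_steps + 1)
                      for k in ("i_na", "i_k", "i_leak", "i_na_pump", "i_k_pump")}
                  for p in cur_idx}
        vmax = v.copy()

        species_name, species_idx = None, None
        species_rec = {}
        if record_species is not None:
            species_name, mask = record_species
            if species_name not in ("Na", "K", "both"):
                raise ValueError("record_species must name 'Na', 'K' or 'both'")
            species_idx = np.flatnonzero(np.asarray(mask, bool))
            wanted = ("Na", "K") if species_name == "both" else (species_name,)
            species_rec = {s: np.empty((n_steps, species_idx.size)) for s in wanted}

        saved_v, saved_t = [], []

        g_leak = self.params.g_leak
        e_leak, e_k, e_na, e_pump = (self.params.e_leak, self.params.e_k,
                                     self.params.e_na, self.params.e_pump)

        def record_currents(step):
            for p, j in cur_idx.items():
                tr = cur_tr[p]
                vj = v[j]
                tr["i_k"][step] = self.g_k[j] * ngate[j] ** 4 * (vj - e_k)
                tr["i_na"][step] = self.g_na[j] * m[j] ** 3 * h[j] * (vj - e_na)
                tr["i_leak"][step] = g_leak * (vj - e_leak)
                tr["i_na_pump"][step] = 3.0 * self.g_pump[j] * (vj - e_pump)
                tr["i_k_pump"][step] = -2.0 * self.g_pump[j] * (vj - e_pump)

        for p, j in probe_idx.items():
            probe_tr[p][0] = v[j]
        record_currents(0)
        if save_v_stride:
            saved_v.append(v.copy())
            saved_t.append(0.0)

        inj_charge = 0.0
        mem_charge = 0.0
        q_cap_start = float(np.sum(c_over_dt * dt * v))

        for step in range(n_steps):
            # exact exponential gate update at frozen V
            a_n, b_n, a_m, b_m, a_h, b_h = mb.gating_rates(v)
            for x, a, b, ph in ((m, a_m, b_m, self.phi_m),
                                (h, a_h, b_h, self.phi_h),
                                (ngate, a_n, b_n, self.phi_n)):
                tot = ph * (a + b)
                xinf = a / (a + b)
                x += (xinf - x) * (-np.expm1(-dt * tot))

            # linear-in-V membrane current at frozen gates
            g_k_eff = self.g_k * ngate ** 4
            g_na_eff = self.g_na * m ** 3 * h
            g_sum = g_k_eff + g_na_eff + g_leak + self.g_pump        # S/cm^2
            ge_sum = (g_k_eff * e_k + g_na_eff * e_na + g_leak * e_leak
                      + self.g_pump * e_pump)
            g_abs = g_sum * self.area_cm2 * 1e6                      # uS
            ge_abs = ge_sum * self.area_cm2 * 1e6                    # nA

            # rhs: C/dt V + Ge + I_inj + (1-theta) * explicit part; for
            # backward Euler (theta=1) the explicit part vanishes
            rhs = c_over_dt * v + ge_abs
            if theta != 1.0:
                expl = -g_abs * v
                dax = (v[1:] - v[:-1]) * inv_ra
                expl[:-1] += dax
                expl[1:] -= dax
                rhs += (1.0 - theta) * expl
            if stim_series is not None and stim_series[step]:
                rhs[stim_seg] += stim_series[step]
                inj_charge += stim_series[step] * dt
            if inj_segs.size:
                vals = np.array([s[step] for s in inj_vals])
                rhs[inj_segs] += vals
                inj_charge += vals.sum() * dt

            ab[1, :] = c_over_dt + theta * (g_abs + inv_l + inv_r)
            v_new = solve_banded((1, 1), ab, rhs)

            mem_charge += float(np.sum(g_abs * v_new - ge_abs)) * dt
            v = v_new
            np.maximum(vmax, v, out=vmax)

            if species_idx is not None:
                ji = species_idx
                if "K" in species_rec:
                    species_rec["K"][step] = (
                        self.g_k[ji] * ngate[ji] ** 4 * (v[ji] - e_k))
                if "Na" in species_rec:
                    species_rec["Na"][step] = (
                        self.g_na[ji] * m[ji] ** 3 * h[ji] * (v[ji] - e_na))

            step1 = step + 1
            for p, j in probe_idx.items():
                probe_tr[p][step1] = v[j]
            record_currents(step1)
            if save_v_stride and step1 % save_v_stride == 0:
                saved_v.append(v.copy())
                saved_t.append(t[step1])

            if step % 200 == 0 and np.max(np.abs(v)) > 200.0:
                raise RuntimeError(
                    f"numerical instability (|V| > 200 mV) at t={t[step1]:.3f} "
                    f"ms; dt={dt}, min dx={self.seg_len_mm.min():.4f} mm")

        if np.max(np.abs(v)) > 200.0 or not np.all(np.isfinite(v)):
            raise RuntimeError(
                f"numerical instability at end of run; dt={dt}, "
                f"min dx={self.seg_len_mm.min():.4f} mm")

        q_cap_end = float(np.sum(c_over_dt * dt * v))
        mem_charge += q_cap_end - q_cap_start

        from .membrane import CurrentBreakdown
        probe_currents = {
            p: CurrentBreakdown(**{k: np.asarray(tr[k]) for k in tr})
            for p, tr in cur_tr.items()
        }
        return SimulationResult(
            t=t,
            x_mm=self.x_mm,
            probe_v={p: probe_tr[p] for p in probe_tr},
            probe_currents=probe_currents,
            vmax=vmax,
            v_rest=v_rest_out,
            v_field=np.asarray(saved_v) if save_v_stride else None,
            t_field=np.asarray(saved_t) if save_v_stride else None,
            injected_charge_nc=inj_charge * 1e-3,    # nA*ms = pC; /1e3 -> nC
            membrane_charge_nc=mem_charge * 1e-3,
            metadata={
                "dt": dt, "t_end": t_end, "variant": self.variant,
                "diameter_um": self.diameter_um, "n_seg": n,
                "theta": theta,
            },
            species_record=species_rec or None,
            species_segments=species_idx,
        )


def run_simulation(axon: AxonModel, stim: StimulusProtocol | None, dt: float,
                   t_end: float, injected_currents=None, **kw) -> SimulationResult:
    """Functional wrapper around :meth:`AxonModel.simulate`."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return axon.simulate(stim=stim, dt=dt, t_end=t_end,
                         injected_currents=injected_currents, **kw)
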