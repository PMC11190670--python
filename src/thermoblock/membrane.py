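"""Point-membrane physics of the squid giant axon at arbitrary temperature.

Two model variants are supported:

``original_HH``
    The classic Hodgkin/Huxley membrane with fixed peak conductances, no
    electrogenic pump, a single Q10 of 3 applied to all three gates, and a
    fixed axial resistivity.

``modified_HH``
    The temperature-extended membrane: per-gate piecewise Q10 factors fitted
    over 5-25 degC, Gaussian-of-temperature peak conductances, an electrogenic
    3Na/2K pump with its own Q10, and an exponentially temperature-dependent
    axial resistivity.

Internal unit conventions (used consistently across the package):
voltage mV, time ms, conductance density S cm^-2, current density mA cm^-2,
specific capacitance uF cm^-2, temperature degC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GatingState",
    "MembraneParams",
    "CurrentBreakdown",
    "gating_rates",
    "steady_state_gates",
    "phi",
    "q10_rate",
    "peak_conductances",
    "pump_conductance",
    "pump_currents",
    "membrane_current",
    "gate_derivatives",
    "resting_state",
]

MODIFIED = "modified_HH"
ORIGINAL = "original_HH"
GATES = ("m", "h", "n")

# Temperature interval edges for the piecewise Q10 factors (degC).
Q10_BREAKPOINTS = (10.0, 15.0, 20.0)


@dataclass
class GatingState:
    """Activation/inactivation gate fractions, each in [0, 1].

    m: sodium activation, h: sodium inactivation, n: potassium activation.
    Fields may be scalars or per-segment arrays.
    """

    m: np.ndarray | float
    h: np.ndarray | float
    n: np.ndarray | float

    def clip(self) -> "GatingState":
        return GatingState(
            np.clip(self.m, 0.0, 1.0),
            np.clip(self.h, 0.0, 1.0),
            np.clip(self.n, 0.0, 1.0),
        )


@dataclass(frozen=True)
class MembraneParams:
    """All fixed and temperature-law coefficients of the membrane model.

    Defaults reproduce the fixed-parameter table of the modified model:
    gL = 0.3 mS cm^-2, Cm = 1 uF cm^-2, gNaK = 7 uS cm^-2, Epump = -220 mV,
    EL = -51 mV, EK = -74 mV, ENa = 53 mV, base temperature 6.3 degC.
    Both variants share the reversal potentials; they differ in conductance
    laws, pump, gate Q10s and axial resistivity.
    """

    model_variant: str = MODIFIED
    g_leak: float = 0.3e-3        # S cm^-2
    c_m: float = 1.0              # uF cm^-2
    e_leak: float = -51.0         # mV
    e_k: float = -74.0            # mV
    e_na: float = 53.0            # mV
    e_pump: float = -220.0        # mV
    g_pump_initial: float = 7e-6  # S cm^-2 at base temperature
    pump_q10: float = 1.88
    base_temp: float = 6.3        # degC
    # Fixed peak conductances used only by the original variant (S cm^-2).
    fixed_g_k: float = 0.036
    fixed_g_na: float = 0.120
    # Per-gate Q10 for intervals (<=10], (10,15], (15,20], (20,25+] degC.
    q10_m: tuple = (3.0, 3.0, 2.8, 2.7)
    q10_h: tuple = (3.0, 2.9, 3.0, 3.0)
    q10_n: tuple = (3.0, 2.8, 2.4, 2.3)
    # Gaussian peak-conductance laws gmax(T) = peak * exp(-((T-center)/width)^2).
    gk_peak: float = 1.60         # S cm^-2
    gk_center: float = 27.88      # degC
    gk_width: float = 12.85       # degC
    gna_peak: float = 0.42
    gna_center: float = 31.83
    gna_width: float = 31.62
    # Axial resistivity law Ra(T) = ra_coeff * exp(-ra_decay * T) (ohm cm);
    # the original variant uses the fixed value.
    ra_coeff: float = 56.84
    ra_decay: float = 0.03        # 1/degC
    ra_fixed: float = 35.4        # ohm cm

    def __post_init__(self):
        if self.model_variant not in (MODIFIED, ORIGINAL):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        for name in ("g_leak", "g_pump_initial", "fixed_g_k", "fixed_g_na"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def q10_table(self, gate: str) -> tuple:
        try:
            return {"m": self.q10_m, "h": self.q10_h, "n": self.q10_n}[gate]
        except KeyError:
            raise ValueError(f"unknown gate {gate!r}") from None

    def replace(self, **kw) -> "MembraneParams":
        return dataclasses.replace(self, **kw)

    @classmethod
    def original(cls, **kw) -> "MembraneParams":
        return cls(model_variant=ORIGINAL, **kw)


@dataclass
class CurrentBreakdown:
    """Per-species membrane current densities, mA cm^-2, outward positive."""

    i_na: np.ndarray | float
    i_k: np.ndarray | float
    i_leak: np.ndarray | float
    i_na_pump: np.ndarray | float
    i_k_pump: np.ndarray | float

    @property
    def i_total(self):
        return self.i_na + self.i_k + self.i_leak + self.i_na_pump + self.i_k_pump


def _vtrap(u, scale):
    # u / (1 - exp(-u/scale)) with the removable singularity at u = 0 replaced
    # by its two-term series scale * (1 + u/(2*scale)).
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        out = safe / (1.0 - np.exp(-safe / scale))
    series = scale * (1.0 + u / (2.0 * scale))
    return np.where(small, series, out)


def gating_rates(v):
    """Voltage-dependent rate constants (alpha_n, beta_n, alpha_m, beta_m,
    alpha_h, beta_h) in ms^-1 at the base temperature.

    The removable 0/0 singularities at V = -55 mV (alpha_n) and V = -40 mV
    (alpha_m) evaluate to their limits 0.1 and 1.0 ms^-1.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    a_n = 0.01 * _vtrap(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    a_m = 0.1 * _vtrap(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


def steady_state_gates(v) -> GatingState:
    """Gate values x_inf = alpha/(alpha+beta) at fixed potential."""
    a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(v)
    return GatingState(m=a_m / (a_m + b_m), h=a_h / (a_h + b_h), n=a_n / (a_n + b_n))


def q10_rate(r1, q10, t1, t2):
    """Scale a rate from temperature t1 to t2: R2 = R1 * Q10**((T2-T1)/10)."""
    if np.any(np.asarray(q10) <= 0):
        raise ValueError("Q10 must be positive")
    return np.asarray(r1) * np.asarray(q10) ** ((np.asarray(t2) - np.asarray(t1)) / 10.0)


def phi(temperature, gate: str, params: MembraneParams):
    """Multiplicative temperature factor for a gate's kinetics.

    For the original variant this is 3**((T-6.3)/10) for every gate. For the
    modified variant it is the piecewise-continuous product of per-interval
    Q10 factors with breakpoints at 10, 15 and 20 degC; above the last fitted
    interval the final interval's Q10 is extrapolated.
    """
    t = np.asarray(temperature, dtype=float)
    if params.model_variant == ORIGINAL:
        return 3.0 ** ((t - params.base_temp) / 10.0)
    q = np.asarray(params.q10_table(gate), dtype=float)
    bps = np.asarray(Q10_BREAKPOINTS)
    knots = np.concatenate(([params.base_temp], bps))
    # cumulative factor at the left knot of each interval
    cum = np.ones(len(q))
    for k in range(1, len(q)):
        cum[k] = cum[k - 1] * q[k - 1] ** ((knots[k] - knots[k - 1]) / 10.0)
    idx = np.searchsorted(bps, t, side="left")
    out = cum[idx] * q[idx] ** ((t - knots[idx]) / 10.0)
    return out if out.ndim else float(out)


def peak_conductances(temperature, params: MembraneParams):
    """Peak potassium and sodium conductances (gKmax, gNamax) in S cm^-2.

    Gaussian functions of temperature for the modified variant; the fixed
    Hodgkin/Huxley constants, independent of temperature, for the original.
    """
    t = np.asarray(temperature, dtype=float)
    if params.model_variant == ORIGINAL:
        shape = np.broadcast_shapes(t.shape)
        g_k = np.broadcast_to(params.fixed_g_k, shape).copy() if t.ndim else params.fixed_g_k
        g_na = np.broadcast_to(params.fixed_g_na, shape).copy() if t.ndim else params.fixed_g_na
        return g_k, g_na
    g_k = params.gk_peak * np.exp(-(((t - params.gk_center) / params.gk_width) ** 2))
    g_na = params.gna_peak * np.exp(-(((t - params.gna_center) / params.gna_width) ** 2))
    if not t.ndim:
        return float(g_k), float(g_na)
    return g_k, g_na


def pump_conductance(temperature, params: MembraneParams):
    """Pump conductance gNaK(T) in S cm^-2 (zero for the original variant)."""
    t = np.asarray(temperature, dtype=float)
    if params.model_variant == ORIGINAL:
        out = np.zeros_like(t)
        return out if t.ndim else 0.0
    out = params.g_pump_initial * params.pump_q10 ** ((t - params.base_temp) / 10.0)
    return out if t.ndim else float(out)


def pump_currents(v, temperature, params: MembraneParams):
    """Electrogenic pump currents (I_Na_pump, I_K_pump) in mA cm^-2.

    3:2 stoichiometry: I_Na_pump = 3 g(T)(V - Epump), I_K_pump = -2 g(T)(V - Epump);
    the net pump current g(T)(V - Epump) is outward for V > Epump.
    """
    g = pump_conductance(temperature, params)
    drive = np.asarray(v, dtype=float) - params.e_pump
    i_na = 3.0 * g * drive
    i_k = -2.0 * g * drive
    if np.ndim(i_na):
        return i_na, i_k
    return float(i_na), float(i_k)


def membrane_current(
    v,
    gates: GatingState,
    temperature,
    params: MembraneParams,
    gk_scale=1.0,
    gna_scale=1.0,
) -> CurrentBreakdown:
    """Total ionic membrane current density and its components (mA cm^-2,
    outward positive). Axial and stimulus terms belong to the cable solver.

    ``gk_scale``/``gna_scale`` scale the voltage-gated peak conductances and
    implement region-wise channel ablation.
    """
    g_k_max, g_na_max = peak_conductances(temperature, params)
    i_k = gk_scale * g_k_max * np.asarray(gates.n) ** 4 * (v - params.e_k)
    i_na = gna_scale * g_na_max * np.asarray(gates.m) ** 3 * np.asarray(gates.h) * (v - params.e_na)
    i_leak = params.g_leak * (np.asarray(v) - params.e_leak)
    i_na_pump, i_k_pump = pump_currents(v, temperature, params)
    return CurrentBreakdown(i_na=i_na, i_k=i_k, i_leak=i_leak,
                            i_na_pump=i_na_pump, i_k_pump=i_k_pump)


def gate_derivatives(v, gates: GatingState, temperature, params: MembraneParams):
    """(dm/dt, dh/dt, dn/dt) in ms^-1: dx/dt = phi_x(T)(alpha_x(1-x) - beta_x x)."""
    a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(v)
    dm = phi(temperature, "m", params) * (a_m * (1.0 - gates.m) - b_m * gates.m)
    dh = phi(temperature, "h", params) * (a_h * (1.0 - gates.h) - b_h * gates.h)
    dn = phi(temperature, "n", params) * (a_n * (1.0 - gates.n) - b_n * gates.n)
    return dm, dh, dn


def _rest_residual(v, temperature, params, gk_scale, gna_scale):
    gates = steady_state_gates(v)
    return membrane_current(v, gates, temperature, params, gk_scale, gna_scale).i_total


def resting_state(temperature, params: MembraneParams, gk_scale=1.0, gna_scale=1.0):
    """Resting potential and steady-state gates by root-finding the total
    membrane current with gates at their steady state.

    Scans -90..+40 mV for sign changes and returns the most hyperpolarized
    stable root (one with locally increasing outward current). This replaces
    a long settling run; the cable solver also supports explicit settling.
    An isolated potassium-ablated membrane rests far depolarized (near or
    above 0 mV); in a cable that region is pulled back by axial coupling.
    """
    grid = np.arange(-90.0, 40.1, 0.5)
    vals = np.array([
        _rest_residual(v, temperature, params, gk_scale, gna_scale) for v in grid
    ])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            r = brentq(_rest_residual, grid[i], grid[i + 1],
                       args=(temperature, params, gk_scale, gna_scale),
                       xtol=1e-10)
            # stable iff residual slope (dI/dV) positive at the root
            eps = 1e-4
            slope = (_rest_residual(r + eps, temperature, params, gk_scale, gna_scale)
                     - _rest_residual(r - eps, temperature, params, gk_scale, gna_scale))
            if slope > 0:
                roots.append(r)
    if not roots:
        raise RuntimeError(
            f"no stable resting potential found in [-90, 40] mV at T={temperature}"
        )
    v_rest = float(min(roots))
    return v_rest, steady_state_gates(v_rest)
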