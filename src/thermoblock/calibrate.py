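"""Parameter-fitting machinery: grid searches over per-interval gate Q10s
and peak conductances against reference rate-of-rise/fall tables, axial
resistivity tuning against conduction velocity, and error-bar propagation.

The fitting classes follow the Model / fit() / Results idiom: construct a
search from a :class:`ReferenceTable` and a :class:`GridSearchSpec`, call
``fit()``, and read estimates and diagnostics off the returned results
object (``summary()`` prints a table).

Rates of rise and fall are measured on the propagating AP of a
standardized short uniform cable (batched across parameter grids); the
synthetic-reference generator uses the identical protocol, so noise-free
round-trip parameter recovery is exact. All searches are deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import membrane as mb
from .membrane import MembraneParams, MODIFIED, ORIGINAL, Q10_BREAKPOINTS

__all__ = [
    "ReferenceTable",
    "GridSearchSpec",
    "PatchProtocol",
    "patch_response",
    "rise_fall_errors",
    "Q10Search",
    "ConductanceSearch",
    "ResistivityFit",
    "propagate_error_bars",
]

REFERENCE_TEMPS = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0)

_COLUMNS = ["temperature_c", "rise", "rise_lower", "rise_upper",
            "fall", "fall_lower", "fall_upper", "amplitude", "velocity",
            "ap_generated"]


@dataclass
class ReferenceTable:
    """Temperature-indexed measurement rows used by calibration.

    Rates of rise are positive, rates of fall are stored as negative signed
    derivatives (V/s); (lower, mean, upper) are numeric bounds with
    lower <= mean <= upper. Amplitude (mV) and conduction velocity (m/s)
    columns are optional (NaN when absent).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _COLUMNS[:7] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"reference table missing columns {missing}")
        for c in _COLUMNS:
            if c not in self.frame.columns:
                self.frame[c] = np.nan if c != "ap_generated" else True
        t = self.frame["temperature_c"].to_numpy()
        if len(np.unique(t)) != len(t):
            raise ValueError("temperatures must be distinct")
        ok = self.frame["ap_generated"].astype(bool)
        for q in ("rise", "fall"):
            lo = self.frame.loc[ok, f"{q}_lower"].to_numpy()
            mean = self.frame.loc[ok, q].to_numpy()
            hi = self.frame.loc[ok, f"{q}_upper"].to_numpy()
            if np.any(lo > mean + 1e-12) or np.any(mean > hi + 1e-12):
                raise ValueError(f"{q} bounds must satisfy lower <= mean <= upper")

    @property
    def temperatures(self) -> np.ndarray:
        return self.frame["temperature_c"].to_numpy()

    def row(self, temperature: float) -> pd.Series:
        idx = np.argmin(np.abs(self.temperatures - temperature))
        if abs(self.temperatures[idx] - temperature) > 1e-9:
            raise KeyError(f"no reference row at T={temperature}")
        return self.frame.iloc[idx]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class GridSearchSpec:
    """Grid-search settings.

    Q10 values run over [1.0, 3.0] in steps of 0.1 per gate per interval;
    conductances over their ranges in steps of 0.02 S cm^-2; candidate Q10
    sets must produce an AP whose amplitude is within the admissibility band
    (default 5%) of the reference amplitude.
    """

    q10_min: float = 1.0
    q10_max: float = 3.0
    q10_step: float = 0.1
    conductance_step: float = 0.02
    gk_range: tuple = (0.02, 1.60)
    gna_range: tuple = (0.02, 0.60)
    amplitude_band: float = 0.05
    temperatures: tuple = REFERENCE_TEMPS
    spontaneous_window_ms: float = 250.0

    def __post_init__(self):
        if self.q10_step <= 0 or self.conductance_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.q10_min > self.q10_max:
            raise ValueError("q10 range must be ordered")

    def q10_values(self) -> np.ndarray:
        n = int(round((self.q10_max - self.q10_min) / self.q10_step)) + 1
        return np.round(np.linspace(self.q10_min, self.q10_max, n), 10)

    def conductance_values(self, which: str) -> np.ndarray:
        lo, hi = self.gk_range if which == "K" else self.gna_range
        n = int(round((hi - lo) / self.conductance_step)) + 1
        return np.round(np.linspace(lo, hi, n), 10)


@dataclass(frozen=True)
class PatchProtocol:
    """Space-clamped membrane protocol (used for the spontaneous-activity
    screen of the conductance search).

    The patch settles, optionally receives a brief current-density pulse,
    and the response is measured; a short blanking window after the
    stimulus excludes the capacitive artifact from the derivative extrema.
    """

    dt: float = 0.01              # ms
    settle_ms: float = 20.0
    stim_density: float = 0.15    # mA cm^-2
    stim_width_ms: float = 0.3
    blank_ms: float = 0.3
    post_ms: float = 30.0


@dataclass(frozen=True)
class CableProtocol:
    """Standardized mini-cable AP protocol for rate measurements.

    Rates of rise and fall are properties of the *propagating* action
    potential (a space-clamped patch fails to spike above about 15 degC
    where the potassium conductance is large, while the propagating AP
    persists), so the calibration observables are measured at a probe on a
    short uniform cable. The same protocol generates synthetic references,
    making noise-free round-trip recovery exact.
    """

    length_mm: float = 10.0
    n_seg: int = 40
    diameter_um: float = 500.0
    dt: float = 0.01
    stim_na: float = 20000.0  # strong drive so initiation never limits
    stim_width_ms: float = 0.5
    probe_frac: float = 0.6
    t_end_ms: float = 8.0
    ra_ohm_cm: float | None = None   # set per temperature by the drivers


def patch_response(phi_m, phi_h, phi_n, g_k, g_na, g_pump,
                   params: MembraneParams, protocol: PatchProtocol = PatchProtocol(),
                   stim_density=None):
    """Simulate N independent membrane patches and measure their APs.

    All per-patch arguments broadcast to a common shape. Returns a dict of
    arrays: v_rest (mV), amplitude (mV), rise and fall (V/s, positive),
    spike (bool; AP peak above 0 mV).
    """
    phi_m, phi_h, phi_n, g_k, g_na, g_pump = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, float))
          for a in (phi_m, phi_h, phi_n, g_k, g_na, g_pump)))
    n = phi_m.size
    shape = phi_m.shape
    phi_m, phi_h, phi_n, g_k, g_na, g_pump = (
        a.ravel() for a in (phi_m, phi_h, phi_n, g_k, g_na, g_pump))

    pr = protocol
    stim = pr.stim_density if stim_density is None else stim_density
    dt = pr.dt
    n_settle = int(round(pr.settle_ms / dt))
    n_stim = int(round(pr.stim_width_ms / dt))
    n_blank = int(round(pr.blank_ms / dt))
    n_post = int(round(pr.post_ms / dt))

    v = np.full(n, -65.0)
    g0 = mb.steady_state_gates(v)
    m, h, ng = (np.asarray(x, float).copy() for x in (g0.m, g0.h, g0.n))

    gl, el, ek, ena, ep, cm = (params.g_leak, params.e_leak, params.e_k,
                               params.e_na, params.e_pump, params.c_m)

    def step(v, i_stim):
        a_n, b_n, a_m, b_m, a_h, b_h = mb.gating_rates(v)
        for x, a, b, ph in ((m, a_m, b_m, phi_m), (h, a_h, b_h, phi_h),
                            (ng, a_n, b_n, phi_n)):
            tot = ph * (a + b)
            x += (a / (a + b) - x) * (-np.expm1(-dt * tot))
        gk_eff = g_k * ng ** 4
        gna_eff = g_na * m ** 3 * h
        g_sum = gk_eff + gna_eff + gl + g_pump
        ge = gk_eff * ek + gna_eff * ena + gl * el + g_pump * ep
        # implicit voltage update; 1e3 converts S/cm^2 * mV -> uA/cm^2
        return (cm / dt * v + 1e3 * (ge + i_stim)) / (cm / dt + 1e3 * g_sum)

    for _ in range(n_settle):
        v = step(v, 0.0)
    v_rest = v.copy()
    for _ in range(n_stim):
        v = step(v, stim)
    for _ in range(n_blank):
        v = step(v, 0.0)

    vmax = v.copy()
    rise = np.zeros(n)
    fall = np.zeros(n)
    v_prev = v.copy()
    for _ in range(n_post):
        v = step(v, 0.0)
        dvdt = (v - v_prev) / dt               # mV/ms = V/s
        np.maximum(rise, dvdt, out=rise)
        np.maximum(fall, -dvdt, out=fall)
        np.maximum(vmax, v, out=vmax)
        v_prev = v.copy()

    out = {
        "v_rest": v_rest, "amplitude": vmax - v_rest,
        "rise": rise, "fall": fall, "spike": vmax > 0.0, "v_peak": vmax,
    }
    return {k: a.reshape(shape) for k, a in out.items()}


def _vector_rest(phi_unused, g_k, g_na, g_pump, params: MembraneParams):
    """Vectorized resting potential by bisection of the steady-state
    membrane current over [-90, -40] mV (phi factors do not move rest)."""

    def f(v):
        g = mb.steady_state_gates(v)
        gk_eff = g_k * np.asarray(g.n) ** 4
        gna_eff = g_na * np.asarray(g.m) ** 3 * np.asarray(g.h)
        return (gk_eff * (v - params.e_k) + gna_eff * (v - params.e_na)
                + params.g_leak * (v - params.e_leak)
                + g_pump * (v - params.e_pump))

    lo = np.full(np.broadcast(g_k, g_na, g_pump).shape, -90.0)
    hi = np.full_like(lo, -40.0)
    f_lo = f(lo)
    bad = f_lo > 0  # no inward current even at -90: fall back to midpoint
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    rest = 0.5 * (lo + hi)
    return np.where(bad, -65.0, rest)


def cable_response(phi_m, phi_h, phi_n, g_k, g_na, g_pump,
                   params: MembraneParams,
                   protocol: CableProtocol = CableProtocol()):
    """Simulate N independent mini-cables (one per parameter set) and
    measure the propagating AP at the probe.

    Per-point membrane parameters broadcast to a common batch shape; each
    batch member is a uniform cable of ``n_seg`` segments integrated by
    backward Euler with a batched Thomas solve. Returns arrays: v_rest,
    amplitude (mV), rise and fall (V/s, positive), spike (peak > 0 mV).
    """
    arrs = [np.atleast_1d(np.asarray(a, float))
            for a in (phi_m, phi_h, phi_n, g_k, g_na, g_pump)]
    phi_m, phi_h, phi_n, g_k, g_na, g_pump = np.broadcast_arrays(*arrs)
    shape = phi_m.shape
    flat = [a.reshape(-1, 1) for a in (phi_m, phi_h, phi_n, g_k, g_na, g_pump)]
    phi_m, phi_h, phi_n, g_k, g_na, g_pump = flat
    nb = phi_m.shape[0]

    pr = protocol
    ns = pr.n_seg
    dt = pr.dt
    seg_len_cm = pr.length_mm / ns / 10.0
    d_cm = pr.diameter_um / 1e4
    area = np.pi * d_cm * seg_len_cm                       # cm^2
    ra_ohm_cm = pr.ra_ohm_cm
    if ra_ohm_cm is None:
        from .cable import axial_resistivity
        ra_ohm_cm = axial_resistivity(params.base_temp, params.model_variant,
                                      params)
    r_cm = d_cm / 2.0
    ra_seg = ra_ohm_cm * seg_len_cm / (np.pi * r_cm ** 2)  # ohm between centers
    inv_ra = 1.0 / (ra_seg / 1e6)                          # uS
    c_over_dt = params.c_m * area * 1e3 / dt               # nA ms/mV / ms

    v0 = _vector_rest(None, g_k, g_na, g_pump, params)     # (nb, 1)
    v = np.repeat(v0, ns, axis=1)
    g0 = mb.steady_state_gates(v)
    m = np.asarray(g0.m).copy()
    h = np.asarray(g0.h).copy()
    ng = np.asarray(g0.n).copy()
    v_rest = v[:, int(pr.probe_frac * ns)].copy()

    gl, el, ek, ena, ep = (params.g_leak, params.e_leak, params.e_k,
                           params.e_na, params.e_pump)
    n_steps = int(round(pr.t_end_ms / dt))
    n_stim = int(round(pr.stim_width_ms / dt))
    probe = int(pr.probe_frac * ns)

    # Thomas solver workspaces; off-diagonals are constant scalars
    low = np.full(ns, -inv_ra)
    low[0] = 0.0
    up = np.full(ns, -inv_ra)
    up[-1] = 0.0
    inv_sum = np.full(ns, 2.0 * inv_ra)
    inv_sum[0] = inv_sum[-1] = inv_ra

    cp = np.empty((nb, ns))
    dp = np.empty((nb, ns))

    vmax = v[:, probe].copy()
    rise = np.zeros(nb)
    fall = np.zeros(nb)
    v_prev = v[:, probe].copy()

    for step in range(n_steps):
        a_n, b_n, a_m, b_m, a_h, b_h = mb.gating_rates(v)
        for x, a, b, ph in ((m, a_m, b_m, phi_m), (h, a_h, b_h, phi_h),
                            (ng, a_n, b_n, phi_n)):
            tot = ph * (a + b)
            x += (a / (a + b) - x) * (-np.expm1(-dt * tot))
        gk_eff = g_k * ng ** 4
        gna_eff = g_na * m ** 3 * h
        g_sum = gk_eff + gna_eff + gl + g_pump
        ge = gk_eff * ek + gna_eff * ena + gl * el + g_pump * ep
        g_abs = g_sum * area * 1e6
        ge_abs = ge * area * 1e6
        rhs = c_over_dt * v + ge_abs
        if step < n_stim:
            rhs[:, 0] += pr.stim_na
        diag = c_over_dt + g_abs + inv_sum

        # batched Thomas
        cp[:, 0] = up[0] / diag[:, 0]
        dp[:, 0] = rhs[:, 0] / diag[:, 0]
        for i in range(1, ns):
            denom = diag[:, i] - low[i] * cp[:, i - 1]
            cp[:, i] = up[i] / denom
            dp[:, i] = (rhs[:, i] - low[i] * dp[:, i - 1]) / denom
        v[:, -1] = dp[:, -1]
        for i in range(ns - 2, -1, -1):
            v[:, i] = dp[:, i] - cp[:, i] * v[:, i + 1]

        vp = v[:, probe]
        dvdt = (vp - v_prev) / dt
        np.maximum(rise, dvdt, out=rise)
        np.maximum(fall, -dvdt, out=fall)
        np.maximum(vmax, vp, out=vmax)
        v_prev = vp.copy()

    out = {"v_rest": v_rest, "amplitude": vmax - v_rest, "rise": rise,
           "fall": fall, "spike": vmax > 0.0, "v_peak": vmax}
    return {k: a.reshape(shape) for k, a in out.items()}


def _cable_protocol_at(temperature: float, params: MembraneParams,
                       protocol: CableProtocol) -> CableProtocol:
    """Attach the temperature's axial resistivity to the protocol."""
    from .cable import axial_resistivity
    import dataclasses as _dc

    ra = float(axial_resistivity(temperature, params.model_variant, params))
    return _dc.replace(protocol, ra_ohm_cm=ra)


def model_phi_arrays(temperature: float, params: MembraneParams):
    """(phi_m, phi_h, phi_n) at a temperature from a parameter set."""
    return (mb.phi(temperature, "m", params), mb.phi(temperature, "h", params),
            mb.phi(temperature, "n", params))


def measure_rates(temperature: float, params: MembraneParams,
                  protocol: CableProtocol = CableProtocol()):
    """Mini-cable rise/fall/amplitude at one temperature for a parameter set."""
    pm, ph, pn = model_phi_arrays(temperature, params)
    g_k, g_na = mb.peak_conductances(temperature, params)
    g_p = mb.pump_conductance(temperature, params)
    pr = _cable_protocol_at(temperature, params, protocol)
    r = cable_response(pm, ph, pn, g_k, g_na, g_p, params, pr)
    return {k: float(np.asarray(v).ravel()[0]) for k, v in r.items()}


def rise_fall_errors(ref: ReferenceTable, model_rates: dict):
    """Per-temperature absolute relative errors and the total squared error.

    ``model_rates`` maps temperature -> (rise, fall) with fall signed like
    the table (negative). Etotal = sum(Erise^2) + sum(Efall^2).
    """
    e_rise, e_fall = {}, {}
    for t, (rest, fest) in model_rates.items():
        row = ref.row(t)
        rexp, fexp = float(row["rise"]), float(row["fall"])
        if rexp == 0 or fexp == 0:
            raise ZeroDivisionError(f"zero reference rate at T={t}")
        e_rise[t] = abs((rexp - rest) / rexp)
        e_fall[t] = abs((fexp - fest) / fexp)
    etotal = sum(v ** 2 for v in e_rise.values()) + sum(v ** 2 for v in e_fall.values())
    return e_rise, e_fall, float(etotal)


def _interval_index(temperature: float) -> int:
    return int(np.searchsorted(np.asarray(Q10_BREAKPOINTS), temperature, side="left"))


@dataclass
class Q10SearchResults:
    """Per-interval best (Q10_m, Q10_h, Q10_n) with diagnostics."""

    params: MembraneParams
    per_interval: dict            # interval index -> dict
    spec: GridSearchSpec

    def summary(self) -> str:
        knots = (6.3,) + Q10_BREAKPOINTS
        lines = ["Q10 grid search", f"{'interval':>12} {'Q10_m':>6} {'Q10_h':>6} "
                 f"{'Q10_n':>6} {'Etotal':>10} {'feasible':>9}"]
        for k, info in sorted(self.per_interval.items()):
            qm, qh, qn = info["q10"]
            lines.append(f"{knots[k]:>5.1f}-{(knots + (25.0,))[k + 1]:<5.1f} "
                         f"{qm:>6.1f} {qh:>6.1f} {qn:>6.1f} "
                         f"{info['etotal']:>10.4g} {info['n_feasible']:>9d}")
        return "\n".join(lines)


class Q10Search:
    """Grid search for per-interval gate Q10 values (Model/fit idiom).

    Searches each temperature interval that the reference table covers,
    from the lowest up, holding already-fitted lower intervals fixed; the
    first interval (<= 10 degC) keeps the Hodgkin/Huxley value of 3.
    Candidates must produce an AP with amplitude inside the admissibility
    band; among feasible candidates the one minimizing Etotal wins, ties
    broken by lexicographically smallest (Q10_m, Q10_h, Q10_n).
    """

    def __init__(self, reference: ReferenceTable,
                 spec: GridSearchSpec = GridSearchSpec(),
                 params: MembraneParams | None = None,
                 protocol: CableProtocol = CableProtocol()):
        self.reference = reference
        self.spec = spec
        self.params = params or MembraneParams()
        self.protocol = protocol

    def fit(self) -> Q10SearchResults:
        spec, ref = self.spec, self.reference
        qvals = spec.q10_values()
        grid = np.array(list(itertools.product(qvals, qvals, qvals)))
        fitted = {g: list(self.params.q10_table(g)) for g in ("m", "h", "n")}
        knots = (self.params.base_temp,) + Q10_BREAKPOINTS
        per_interval = {}

        temps = [t for t in ref.temperatures
                 if bool(ref.row(t)["ap_generated"])]
        for k in (1, 2, 3):
            lo = knots[k]
            hi = knots[k + 1] if k + 1 < len(knots) else np.inf
            k_temps = [t for t in temps if lo < t <= hi or (k == 3 and t > lo)]
            if not k_temps:
                continue
            # cumulative factor at this interval's left knot per gate
            cum = {}
            for g in ("m", "h", "n"):
                c = 1.0
                for j in range(1, k):
                    c *= fitted[g][j] ** ((knots[j + 1] - knots[j]) / 10.0)
                c *= fitted[g][0] ** ((knots[1] - knots[0]) / 10.0)
                cum[g] = c
            feasible = np.ones(len(grid), bool)
            etotal = np.zeros(len(grid))
            for t in k_temps:
                expo = (t - lo) / 10.0
                pm = cum["m"] * grid[:, 0] ** expo
                ph = cum["h"] * grid[:, 1] ** expo
                pn = cum["n"] * grid[:, 2] ** expo
                g_k, g_na = mb.peak_conductances(t, self.params)
                g_p = mb.pump_conductance(t, self.params)
                r = cable_response(pm, ph, pn, g_k, g_na, g_p, self.params,
                                   _cable_protocol_at(t, self.params,
                                                      self.protocol))
                row = ref.row(t)
                feasible &= r["spike"]
                amp_ref = float(row["amplitude"])
                if np.isfinite(amp_ref):
                    feasible &= (np.abs(r["amplitude"] - amp_ref) / amp_ref
                                 <= spec.amplitude_band)
                rexp, fexp = float(row["rise"]), float(row["fall"])
                if rexp == 0 or fexp == 0:
                    raise ZeroDivisionError(f"zero reference rate at T={t}")
                etotal += ((rexp - r["rise"]) / rexp) ** 2
                etotal += ((fexp - (-r["fall"])) / fexp) ** 2
            if not feasible.any():
                raise RuntimeError(
                    f"empty feasible set in interval {lo}-{hi} degC "
                    "(no candidate passed the AP/amplitude screens)")
            masked = np.where(feasible, etotal, np.inf)
            best_val = masked.min()
            tied = np.flatnonzero(masked == best_val)
            # lexicographically smallest among exact ties
            order = np.lexsort((grid[tied, 2], grid[tied, 1], grid[tied, 0]))
            best = tied[order[0]]
            qm, qh, qn = grid[best]
            for g, val in zip(("m", "h", "n"), (qm, qh, qn)):
                fitted[g][k] = float(val)
            per_interval[k] = {
                "q10": (float(qm), float(qh), float(qn)),
                "etotal": float(best_val),
                "n_feasible": int(feasible.sum()),
                "temperatures": tuple(k_temps),
            }

        params = self.params.replace(
            q10_m=tuple(fitted["m"]), q10_h=tuple(fitted["h"]),
            q10_n=tuple(fitted["n"]))
        return Q10SearchResults(params=params, per_interval=per_interval,
                                spec=spec)


@dataclass
class ConductanceSearchResults:
    """Per-temperature optimal (gKmax, gNamax) with a Gaussian-law fit."""

    table: pd.DataFrame           # temperature_c, g_k, g_na, error
    gk_fit: tuple | None          # (peak, center, width) of Gaussian fit
    gna_fit: tuple | None

    def summary(self) -> str:
        lines = ["peak-conductance grid search",
                 f"{'T (degC)':>9} {'gKmax':>8} {'gNamax':>8} {'error':>10}"]
        for _, r in self.table.iterrows():
            lines.append(f"{r.temperature_c:>9.1f} {r.g_k:>8.3f} "
                         f"{r.g_na:>8.3f} {r.error:>10.4g}")
        if self.gk_fit is not None:
            p, c, w = self.gk_fit
            lines.append(f"gKmax(T) ~ {p:.3f} exp(-((T-{c:.2f})/{w:.2f})^2)")
        if self.gna_fit is not None:
            p, c, w = self.gna_fit
            lines.append(f"gNamax(T) ~ {p:.3f} exp(-((T-{c:.2f})/{w:.2f})^2)")
        return "\n".join(lines)


class ConductanceSearch:
    """Per-temperature grid search over peak conductances (Model/fit idiom).

    Excludes pairs that fire spontaneously without stimulus (potassium
    conductance too small for a stable rest) or fail to fire with stimulus
    (potassium overwhelming sodium); minimizes the temperature's squared
    rise/fall error. A Gaussian fit across the per-temperature optima
    reproduces the form of the conductance laws.
    """

    def __init__(self, reference: ReferenceTable,
                 spec: GridSearchSpec = GridSearchSpec(),
                 params: MembraneParams | None = None,
                 protocol: CableProtocol = CableProtocol()):
        self.reference = reference
        self.spec = spec
        self.params = params or MembraneParams()
        self.protocol = protocol

    def fit_at(self, temperature: float):
        spec = self.spec
        gk = spec.conductance_values("K")
        gna = spec.conductance_values("Na")
        gg_k, gg_na = (a.ravel() for a in np.meshgrid(gk, gna, indexing="ij"))
        pm, ph, pn = model_phi_arrays(temperature, self.params)
        g_p = mb.pump_conductance(temperature, self.params)

        # failure 1: spontaneous activity with no stimulus (membrane-local,
        # screened on space-clamped patches)
        quiet_proto = PatchProtocol(
            dt=self.protocol.dt, settle_ms=0.0, stim_density=0.0,
            stim_width_ms=self.protocol.dt, blank_ms=0.0,
            post_ms=spec.spontaneous_window_ms)
        quiet = patch_response(pm, ph, pn, gg_k, gg_na, g_p, self.params,
                               quiet_proto)
        spontaneous = quiet["spike"]
        # failure 2: no propagating AP in response to the stimulus
        driven = cable_response(pm, ph, pn, gg_k, gg_na, g_p, self.params,
                                _cable_protocol_at(temperature, self.params,
                                                   self.protocol))
        feasible = ~spontaneous & driven["spike"]
        if not feasible.any():
            raise RuntimeError(
                f"all conductance pairs fail at T={temperature}")
        row = self.reference.row(temperature)
        rexp, fexp = float(row["rise"]), float(row["fall"])
        err = (((rexp - driven["rise"]) / rexp) ** 2
               + ((fexp - (-driven["fall"])) / fexp) ** 2)
        masked = np.where(feasible, err, np.inf)
        tied = np.flatnonzero(masked == masked.min())
        order = np.lexsort((gg_na[tied], gg_k[tied]))
        best = tied[order[0]]
        return float(gg_k[best]), float(gg_na[best]), float(masked.min())

    def fit(self, temperatures=None) -> ConductanceSearchResults:
        temps = (self.reference.temperatures if temperatures is None
                 else np.asarray(temperatures, float))
        rows = []
        for t in temps:
            if not bool(self.reference.row(t)["ap_generated"]):
                continue
            g_k, g_na, err = self.fit_at(float(t))
            rows.append({"temperature_c": float(t), "g_k": g_k,
                         "g_na": g_na, "error": err})
        table = pd.DataFrame(rows)

        def gauss(t, peak, center, width):
            return peak * np.exp(-(((t - center) / width) ** 2))

        gk_fit = gna_fit = None
        if len(table) >= 4:
            try:
                gk_fit = tuple(curve_fit(gauss, table.temperature_c, table.g_k,
                                         p0=(1.6, 28.0, 13.0), maxfev=10000)[0])
                gna_fit = tuple(curve_fit(gauss, table.temperature_c, table.g_na,
                                          p0=(0.4, 32.0, 30.0), maxfev=10000)[0])
            except RuntimeError:
                pass
        return ConductanceSearchResults(table=table, gk_fit=gk_fit,
                                        gna_fit=gna_fit)


@dataclass
class ResistivityFitResults:
    """Per-temperature tuned Ra with an exponential-law fit."""

    table: pd.DataFrame           # temperature_c, ra_ohm_cm, velocity target
    coeff: float | None           # Ra(T) ~ coeff * exp(-decay * T)
    decay: float | None
    r_squared: float | None

    def summary(self) -> str:
        lines = ["axial resistivity tuning",
                 f"{'T (degC)':>9} {'target v':>10} {'Ra':>8}"]
        for _, r in self.table.iterrows():
            lines.append(f"{r.temperature_c:>9.1f} {r.velocity:>10.3f} "
                         f"{r.ra_ohm_cm:>8.2f}")
        if self.coeff is not None:
            lines.append(f"Ra(T) ~ {self.coeff:.2f} exp(-{self.decay:.4f} T), "
                         f"R^2 = {self.r_squared:.3f}")
        return "\n".join(lines)


class ResistivityFit:
    """Tune axial resistivity per temperature against target conduction
    velocities (bisection; velocity is monotone decreasing in Ra), then fit
    Ra(T) to an exponential law.
    """

    def __init__(self, targets: dict, *, params: MembraneParams | None = None,
                 diameter_um: float = 500.0, length_mm: float = 40.0,
                 dt: float = 0.01, rtol: float = 0.01,
                 ra_bounds=(1.0, 500.0)):
        self.targets = dict(targets)
        self.params = params or MembraneParams()
        self.diameter_um = diameter_um
        self.length_mm = length_mm
        self.dt = dt
        self.rtol = rtol
        self.ra_bounds = ra_bounds

    def _velocity(self, temperature: float, ra: float) -> float:
        from .cable import AxonModel, StimulusProtocol, standard_stimulus_amplitude
        from .measure import conduction_velocity

        axon = AxonModel.uniform(temperature, variant=self.params.model_variant,
                                 diameter_um=self.diameter_um,
                                 length_mm=self.length_mm, params=self.params,
                                 ra_override=ra)
        mid = self.length_mm / 2.0
        stim = StimulusProtocol(
            segment=0, amplitude_na=standard_stimulus_amplitude(self.diameter_um),
            width_ms=1.0, onset_ms=5.0)
        t_end = 5.0 + self.length_mm / 1.0 + 5.0
        res = axon.simulate(stim=stim, dt=self.dt, t_end=min(t_end, 60.0),
                            probes=[mid - 8.0, mid + 8.0])
        return conduction_velocity(res, mid - 8.0, mid + 8.0)

    def tune_at(self, temperature: float, target: float) -> float:
        lo, hi = self.ra_bounds
        v_lo = self._velocity(temperature, lo)
        v_hi = self._velocity(temperature, hi)
        if not (v_hi <= target <= v_lo):
            raise RuntimeError(
                f"target velocity {target} m/s unreachable for Ra in "
                f"[{lo}, {hi}] ohm cm at T={temperature}")
        ra = self.params.ra_fixed if self.params.model_variant == ORIGINAL else 35.4
        ra = min(max(ra, lo), hi)
        for _ in range(60):
            v = self._velocity(temperature, ra)
            if abs(v - target) / target <= self.rtol:
                return ra
            if v > target:
                lo = ra
            else:
                hi = ra
            ra = 0.5 * (lo + hi)
        raise RuntimeError("resistivity bisection did not converge")

    def fit(self) -> ResistivityFitResults:
        rows = []
        for t, target in sorted(self.targets.items()):
            rows.append({"temperature_c": float(t), "velocity": float(target),
                         "ra_ohm_cm": self.tune_at(float(t), float(target))})
        table = pd.DataFrame(rows)
        coeff = decay = r2 = None
        if len(table) >= 3:
            b, log_a = np.polyfit(table.temperature_c, np.log(table.ra_ohm_cm), 1)
            coeff, decay = float(np.exp(log_a)), float(-b)
            pred = coeff * np.exp(-decay * table.temperature_c)
            ss_res = float(np.sum((table.ra_ohm_cm - pred) ** 2))
            ss_tot = float(np.sum((table.ra_ohm_cm - table.ra_ohm_cm.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return ResistivityFitResults(table=table, coeff=coeff, decay=decay,
                                     r_squared=r2)


def propagate_error_bars(measurement, param_values, response_values):
    """Map a (lower, mean, upper) measurement through the inverse of a
    locally monotone parameter-response curve.

    ``param_values``/``response_values`` sample the forward response of the
    measured quantity to the parameter near the optimum; the inverse is
    linearly interpolated. Returns an ascending (lower, mean, upper)
    parameter triple. Raises on a non-monotone response.
    """
    lo, mean, hi = (float(v) for v in measurement)
    if not lo <= mean <= hi:
        raise ValueError("measurement triple must be ordered")
    p = np.asarray(param_values, float)
    r = np.asarray(response_values, float)
    order = np.argsort(p)
    p, r = p[order], r[order]
    dr = np.diff(r)
    if np.all(dr > 0):
        pass
    elif np.all(dr < 0):
        p, r = p[::-1], r[::-1]   # make the response ascending for interp
    else:
        raise ValueError("parameter response is not monotone near the optimum")
    if lo < r[0] or hi > r[-1]:
        raise ValueError(
            "measurement outside the sampled response range; extend the "
            "parameter-response curve")
    vals = [float(np.interp(v, r, p)) for v in (lo, mean, hi)]
    out = sorted(vals)
    return out[0], vals[1], out[2]
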