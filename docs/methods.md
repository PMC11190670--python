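# Methods

`thermoblock` simulates action-potential (AP) initiation, propagation and
thermal block in an unmyelinated axon modeled on the squid giant axon. This
note records the model, the numerical choices, the protocol conventions, and
the design decisions taken where the problem was genuinely open.

## The membrane model

Each membrane segment obeys a Hodgkin–Huxley current balance

    Cm dV/dt = −gL(V−EL) − gKmax(T) n⁴(V−EK) − gNamax(T) m³h(V−ENa)
               − INa,pump − IK,pump + Isegment + Istim,

with the classic rate functions αx(V), βx(V) (rest at −65 mV convention;
the removable singularities of αn at −55 mV and αm at −40 mV are evaluated
by a two-term series when |V−V₀| < 10⁻⁶ mV). Gates evolve as
dx/dt = ϕx(T)(αx(1−x) − βx x).

Two variants share the reversal-potential table
(EL = −51, EK = −74, ENa = 53, Epump = −220 mV; gL = 0.3 mS cm⁻²,
Cm = 1 µF cm⁻²):

* **original_HH** — fixed peak conductances gK = 36, gNa = 120 mS cm⁻²,
  no pump, a single Q10 of 3 for all gates (ϕ = 3^((T−6.3)/10)), fixed
  axial resistivity Ra = 35.4 Ω cm. Note that with the shared reversal
  table this variant's isolated rest sits near −63 mV rather than the
  textbook −65 mV; the block criterion (−60 mV) remains conservative.
* **modified_HH** — temperature-dependent extensions:
  - per-gate piecewise Q10 factors ϕm, ϕh, ϕn with breakpoints at 10, 15
    and 20 °C (per-interval Q10s: m: 3, 3, 2.8, 2.7; h: 3, 2.9, 3, 3;
    n: 3, 2.8, 2.4, 2.3). Above 25 °C the last interval's Q10 is
    extrapolated — block experiments reach 40 °C, beyond the fitted range,
    and the package warns when it extrapolates.
  - Gaussian peak-conductance laws
    gKmax(T) = 1.60·exp(−((T−27.88)/12.85)²),
    gNamax(T) = 0.42·exp(−((T−31.83)/31.62)²) S cm⁻².
  - an electrogenic 3Na:2K pump, INa = 3gNaK(T)(V−Epump),
    IK = −2gNaK(T)(V−Epump), with gNaK(T) = 7 µS cm⁻²·1.88^((T−6.3)/10).
    The pump Q10 of 1.88 follows the permeability-ratio derivation; it is
    a parameter (`pump_q10`) for users who prefer a round 2.
  - axial resistivity Ra(T) = 56.84·e^(−0.03T) Ω cm.

Because gKmax(T) peaks at 27.9 °C, block strength in the modified variant
is *not* monotone in temperature above ≈32 °C (kinetic speed-up competes
with declining conductance); monotonicity-based searches and tests use
either the original variant or the monotone sub-range.

## Cable discretization and integrator

The axon (default 100 mm × 500 µm) is divided into cylindrical segments
with sealed ends. Inter-segment resistances are series half-segment
resistances ra(j,j+1) = [Ra(Tj)Lj/2 + Ra(Tj+1)Lj+1/2]/(πr²), so regions of
different temperature automatically couple with the correct local
resistivity. Default segment length is one fortieth of the local passive
length constant λp = √(r/(2 Ra gL)); block searches additionally refine the
heated region to ≤ 1/20 of the candidate length.

Per time step (default dt = 0.01 ms) the gates are advanced by the exact
exponential update at frozen voltage, then the voltage by an implicit
θ-method (backward Euler by default; Crank–Nicolson via `theta=0.5`)
through a tridiagonal solve — unconditionally stable, first-order in time.
A convergence test holds conduction velocity to <1 % under simultaneous
dx and dt halving.

Initial conditions come from per-segment root-finding of the resting
membrane equation (gates at steady state), replacing a long settling run;
heterogeneous-temperature junctions relax during the pre-stimulus window.
An isolated potassium-ablated membrane rests far depolarized, so ablation
protocols start from the *intact* resting profile: with compensation the
clamp holds it, without compensation the region drifts to its shifted rest
during a 25 ms pre-stimulus window and block is classified on the
post-stimulus part of the trace only.

## Measurement conventions

* **Block**: an AP is blocked iff the far-end potential (99 % of length)
  never exceeds −60 mV; touching −60 exactly counts as blocked.
* **Conduction velocity**: half-maximum arrival times (linear
  interpolation) at probes 8 mm either side of the midpoint.
* **Foot time constant**: least-squares fit of V = V₀ + A·e^(t/τ) over a
  window from 0.1 ms before onset (rest + 1 % of |Vrest|) to halfway
  between onset and the maximum-dV/dt time.
* **Length constant**: steady hyperpolarizing current (−50 nA at 500 µm,
  scaled by (d/500)^1.5 to stay quasi-linear) injected at the midpoint;
  λ is the interpolated 1/e decay distance. With a heated region present
  the current is injected well inside the control-temperature flank
  (25 % of length): the region leaves the flank decay essentially
  unchanged (≈0.2 % here, ≈1 % in the published measurement), whereas
  injecting at the region edge mixes the region's lower Ra into the
  profile and inflates the apparent λ by >10 %.
* **Spike trains**: 0 mV upward crossings with a 2 ms refractory merge;
  rate = (count−1)/span.
* **Charge transfer**: trapezoidal integrals of the negative (inward) and
  positive (outward) parts of a current trace, in µC cm⁻² for mA cm⁻²
  inputs.

## Protocol drivers

Searches are bisection over verified monotone brackets: block length to
0.01 mm, block temperature to 0.05 °C, threshold current to 1 % relative.
The heated region is placed centered, starting at the midpoint, or at the
axon's initial segment (initiation block, stimulus inside the region).
Stimuli follow the diameter rule (2000 nA ≥ 10 µm, 100 nA below) unless a
search overrides them.

The repetitive-firing protocol defaults to the original variant, whose
steady-drive (2000 nA) rate is ≈78 Hz; the modified variant's stronger
potassium system fires only once under this drive. Its heated region uses
1.1× the minimum single-AP block length — a region "sufficient to block a
single AP" rather than the marginal minimum, at which train waveforms can
slip through.

Diameter sweeps shorten thin axons (≈20 passive length constants, clipped
to 10–100 mm) — thin axons are tens of thousands of λ long at full length
and the measured quantities are insensitive to length once L ≫ λ. The
initiation-block protocol at exactly-threshold stimulation is scale
invariant: the cable equation rescales length by √d and current by d^1.5,
so the minimum blocking temperature is diameter-independent (a zero-slope
linear relation in √d, R² = 1 by the constant-fit convention). Reported
fits state R² and, for current scaling, the log–log slope.

## Channel ablation and compensatory current

Ablation zeroes gKmax and/or gNamax per segment in a region (TTX/TEA
analogues). The compensatory clamp is record-then-replay: pass 1 simulates
the intact reference axon (same grid; grids must match exactly, replay
never interpolates) and records the ablated species' current in the
region; pass 2 injects the negated record into the ablated axon. The
reference runs *unstimulated* by default: the record is then the resting
current of the missing channels, which restores the control resting
potential without recreating the channels' dynamic response — replaying a
stimulated identical-condition reference would make the ablated axon's
solution identical to the intact one, erasing the contrast the procedure
exists to expose. Clamp fidelity is the mean squared difference of
per-segment peak voltage changes. Because the replayed record is constant
in time, the fidelity is insensitive to step size; the very fine step
sometimes quoted for dynamic-clamp work matters for online clamps, not for
this replay design.

## Calibration

Rates of rise and fall are properties of the *propagating* AP: a
space-clamped patch stops spiking above ≈15 °C where gKmax is large, while
propagating APs persist past 25 °C. Calibration therefore measures rise,
fall and amplitude at a probe on a standardized 10 mm mini-cable
(40 segments, strong 20 000 nA drive so initiation never limits the
measurement), batched across parameter grids with a vectorized tridiagonal
solve. The error functional is Etotal = Σ Erise(Ti)² + Σ Efall(Ti)² with
per-temperature absolute relative errors, over the standard temperature
list {5, 7.5, 10, 12.5, 15, 17.5, 20, 25} °C.

* **Q10 search** (`Q10Search(...).fit()`): per temperature interval, a grid
  over (Q10m, Q10h, Q10n) ∈ [1, 3] step 0.1; candidates must spike and
  match the reference amplitude within 5 %; lowest Etotal wins, ties broken
  lexicographically. Intervals are fitted lowest-first with lower intervals
  held fixed.
* **Conductance search**: per temperature, a grid over (gKmax, gNamax) in
  0.02 S cm⁻² steps; pairs that fire spontaneously within 250 ms without
  stimulus (gK too small for a stable rest — screened on patches, where
  the instability is local) or fail to spike with stimulus are excluded.
  A Gaussian fit across per-temperature optima reproduces the
  conductance-law form.
* **Resistivity tuning**: per temperature, bisection on Ra (velocity is
  monotone decreasing in Ra) to 1 % of the target velocity, initialized at
  35.4 Ω cm; an exponential fit across temperatures recovers the Ra(T)
  form.
* **Error-bar propagation**: a (lower, mean, upper) measurement maps
  through the linearly-interpolated inverse of a locally monotone
  parameter-response curve; non-monotone or out-of-range input raises.

## Synthetic references

`generate_reference` runs the same mini-cable protocol under a known
parameter set, adds independent relative Gaussian noise (seeded
`numpy.random.default_rng`; no global state) and emits mean ± k·sd error
bars; rows whose parameters fail to spike are flagged, never dropped. With
zero noise the table equals the model's own measurements exactly, which
makes round-trip parameter recovery the calibration oracle: any
grid-resident truth must be recovered exactly. The generator emulates the
*statistical shape* of digitized physiological measurements (means with
symmetric bars, a handful of temperatures); it does not emulate systematic
digitization error, temperature-correlated noise, or animal-to-animal
variability, so passing recovery tests certify the search machinery, not
fidelity to any real squid data set.

## Problem sizes and tolerances

Default experiments use the full 100 mm × 500 µm axon at dt = 0.01 ms with
λp/40 segments (≈0.23 mm). Test-suite and example runs use shorter axons
(10–50 mm), coarser fixtures, reduced Q10 grids (step 0.5) and one- or
two-temperature references; these sizes are chosen so the full suite runs
in minutes while every check stays on the converged branch of the
dx/dt-refinement studies. Instability (|V| > 200 mV) raises with the
offending dt/dx named.

## Known limitations

* Above 25 °C the ϕ factors are extrapolations; the Gaussian conductance
  laws are fits whose behavior beyond ≈35 °C drives the non-monotone block
  noted above.
* The original-variant rest sits ≈2 mV depolarized of the textbook value
  because both variants share one reversal table.
* Single unbranched cable, sealed ends, no extracellular resistance, no
  channel noise, no TRP/chloride channels, temperature fields are
  prescribed rather than computed from photothermal physics.
* The minimum centered block length for the modified model converges to
  ≈1.17 mm at 29.5 °C, between the two values (0.9 and 1.12 mm) published
  for nearly identical protocols; placement (centered vs midpoint-start)
  provably does not change the minimum here.
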