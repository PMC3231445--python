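# Methods

`gasbiosense` models the response of an optical gas biosensor whose
receptor sits in a thin aqueous layer behind a gas–liquid interface. The
signal chain is decomposed into four sequential steps plus an optical
readout, each with an explicit closed-form description. The reference
scenario throughout is methanethiol detection by cytochrome c
immobilized in a porous SnO₂ layer under a gelatin cover.

## Model

**Step A — gas–liquid partition.** At equilibrium the dissolved analyte
concentration follows Henry's law, c = k_H·p, with the partial pressure
p obtained from the mixing ratio as p = ppm × 10⁻⁶ × p_total (ppm is a
mole fraction; this is the only interpretation consistent with
100 ppm at 1 atm and k_H = 0.39 M/atm yielding ~40 μM). The aqueous
Henry constant is applied to the hydrogel unchanged, on the grounds of
its high water content; a multiplicative `gel_partition_factor`
(default 1.0) is exposed for users who disagree. Temperature is carried
as metadata only — constants are used at the temperature they were
supplied for, with no van 't Hoff correction.

**Step B — speciation.** Thiol redox chemistry is carried by the
thiolate anion, so the active concentration is the dissociation
equilibrium's anion branch. Two fractions are available:
`paper_approx`, 10^(pH−pKa), which treats the undissociated acid as the
total (valid for pH ≪ pKa and the default, because it reproduces the
conventional hand calculation); and `exact`,
K_a/(K_a + [H⁺]), the Henderson–Hasselbalch mass balance, which stays
in (0, 1) at any pH. Their relative difference is exactly 10^(pH−pKa),
so they agree to 0.1 % whenever pH < pKa − 3; `paper_approx` warns once
pH ≥ pKa, where it exceeds 1. The pH is fixed by the buffer (no proton
balance is solved) and the thiolate pool is treated as
quasi-equilibrated during reaction — replenishment from the 2000-fold
larger thiol reservoir is assumed fast relative to the signalling
reaction.

**Step C — diffusion.** Transport into the layer obeys Fick's second
law with (i) constant D, (ii) instantaneous interface equilibration to
c₀ and zero analyte elsewhere at t = 0, (iii) constant interface
concentration (continuous gas supply). Under these the semi-infinite
solution c(x,t) = c₀(1 − erf(x/2√(Dt))) applies; it is used for the
finite 2.7 μm layer as well, which is conservative — a reflecting far
boundary could only speed equilibration, so a finite-slab series
solution is deliberately out of scope. The porous sensing layer is
treated as bulk liquid (tortuosity 1.0 by default, overridable). The
x = 0, t = 0 corner is defined as c₀ (the interface boundary condition
takes precedence over the initial condition). Equilibration is
summarized by t₉₀, inverted in closed form as
t = (x/2·erfinv(1−f))²/D; for the reference layer (x = 2.7 μm,
D = 1.3 × 10⁻⁹ m²/s) t₉₀ ≈ 0.18 s and the layer bottom reaches 94 % of
c₀ by 0.5 s. Diffusion is *reported*, not coupled into the rate: the
kinetic step assumes the analyte homogeneous at its equilibrium
concentration, consistent with equilibration being ~100× faster than
the minutes-scale signal observation.

**Step D — kinetics.** The signal-generating reaction is a bimolecular
electron transfer, modelled by the second-order law
v = k·[anion]·[receptor_ox] with v in μM/s and k in μM⁻¹s⁻¹. The
receptor concentration is the *effective bulk* value — immobilized
amount divided by the geometric layer volume, treated as a homogeneous
solution. This is physically idealized (the protein sits on pore
surfaces) but is the standard treatment that makes bulk kinetics
applicable. The reference k = 2.8 × 10⁻³ μM⁻¹s⁻¹ was determined with a
surrogate thiol (mercaptoethanol, pKa 9.7) because methanethiol's
volatility frustrates accurate solution preparation; the surrogacy
error is acknowledged, not modelled, and since the underlying
calibration points are not published the constant is consumed as given,
never re-derived.

**Readout.** Beer–Lambert: A = ε·c·d, and for rates
signal [AU/min] = v·Δε·d·60. Δε is the reduced-minus-oxidized
*difference* absorption coefficient at the readout wavelength
(22 mM⁻¹cm⁻¹ at 550 nm for immobilized cytochrome c); the optical path
through the porous layer is the geometric thickness (2.5 μm), with no
porosity correction. A cuvette-style ε in M⁻¹cm⁻¹ is accepted
unit-checked for receptor quantification; note that the 408 nm
coefficient of cytochrome c is sometimes quoted as 1.05 × 10⁵ in
mM⁻¹cm⁻¹ where the magnitude suggests M⁻¹cm⁻¹ — values are consumed
verbatim in whichever unit the user tags them with, and this
discrepancy is documented rather than resolved.

## Chaining modes

`exact_chain` (default) propagates unrounded values:
39 μM → 19.55 nM → 0.547 μM/s → 1.81 × 10⁻⁴ AU/min for the reference
scenario. `paper_rounding` rounds each step's headline value to its
conventional reporting precision before feeding the next step — one
significant figure for the dissolved concentration and the rate, two
for the anion concentration and the final signal — reproducing the
hand-calculated chain 40 μM → 20 nM → 0.6 μM/s → 2.0 × 10⁻⁴ AU/min.
The two modes differ by ~11 % on the reference signal, which bounds the
rounding sensitivity of such chains. The measured reference response,
3.6 × 10⁻⁴ ± 0.4 × 10⁻⁴ AU/min, ships as a documented comparison
constant (`prediction.MEASURED_SIGNAL`) only; it requires the physical
sensor and is never computed.

A prediction is flagged diffusion-limited when t₉₀ exceeds one tenth of
the signal observation timescale (60 s by default). No quantitative
criterion is standard here; both numbers are explicit options, and the
reference scenario sits 30× below the flag.

## Parameters of the reference preset (`methanethiol_cytc`)

| parameter | value | meaning |
|---|---|---|
| mixing ratio | 100 ppm | analyte mole fraction ×10⁻⁶ in the gas |
| total pressure | 1 atm | gas sample pressure |
| k_H | 0.39 M/atm | Henry constant, methanethiol in water |
| pKa | 10.3 | thiol ⇌ thiolate dissociation |
| D | 1.3 × 10⁻⁹ m²/s | aqueous diffusivity (methanol approximation) |
| pH | 7.0 | phosphate-buffered medium |
| receptor | 10 mM | effective bulk cytochrome c in the porous layer |
| sensing layer d | 2.5 μm | porous SnO₂ thickness = optical path |
| cover layer | 200 nm | gelatin film (adds to the diffusion depth) |
| Δε₅₅₀ | 22 mM⁻¹cm⁻¹ | effective difference absorption coefficient |
| k | 2.8 × 10⁻³ μM⁻¹s⁻¹ | second-order rate constant (surrogate-thiol fit) |

## Synthetic data

No public dataset exists for spectroelectrochemical gas-exposure traces
or thiolate calibration series, so the generators in `synthetic_data`
provide fixtures with exactly known ground truth.

`simulate_trace` produces an exposure-protocol absorbance trace: the
mean is piecewise linear — rising at the programmed signal during
gas-ON (zeroth-order appearance of the reduced receptor, valid in the
initial-rate regime; saturation at the ~0.055 AU full-reduction
amplitude can optionally be clipped), flat during OFF, and ramping
linearly back to baseline during an electrochemical RESET — with i.i.d.
Gaussian noise added to every sample. The default protocol is three
exposures with a 60 s reset; the ON/OFF durations (10 min / 2 min) are
fixture choices at the scale of slow optical gas measurements, as
published exposure timings are only graphical. The noise model is the
simplest photometric one and is recorded in the trace metadata;
instrument drift, baseline wander and autocorrelated noise are *not*
emulated, so passing recovery tests demonstrates correctness of the
slope-extraction machinery, not robustness to real-instrument
artefacts.

`simulate_rate_dataset` places initial rates on the second-order
rate-law line and perturbs them with Gaussian noise scaled to the
largest rate. Both generators are deterministic for a fixed seed
(numpy `default_rng`) including byte-identical CSV output.

Monte-Carlo validation sizes: 200 seeded replicates for both the
trace-signal recovery (3 exposures, 2 × 10⁻⁵ AU noise — median recovery
error required < 10 %) and the rate-constant recovery (6 concentrations
spanning 5–100 nM, 5 % rate noise, same tolerance). These sizes give
stable medians while keeping the whole suite in the seconds range.

## Numerical choices

* The finite-difference cross-check (`fd_oracle`) is a forward-time
  centred-space scheme with Dirichlet boundaries (c₀ at the interface,
  zero at a far boundary ≥ 10√(D·t_end) away so the domain is
  effectively semi-infinite). Step sizes violating dt ≤ dx²/(2D) are
  rejected. At the superconvergent ratio D·dt/dx² = 1/6 it agrees with
  the closed form to ~2 × 10⁻⁶ of c₀ on the reference scenario;
  the validation suites require 10⁻³ at all grid points beyond the
  first two nodes (errors are scaled by c₀, since the relative error of
  near-zero tail concentrations is not meaningful).
* Rate fits use ordinary least squares. The default mode is
  `free_intercept` — the regression form behind published calibration
  plots is ambiguous, and a free intercept surfaces offset artefacts —
  with `through_origin` available since the rate law forces a zero
  intercept; through-origin R² is uncentred so it stays in [0, 1].
* Trace slope windows drop the first 1 s after gas-ON (diffusion
  settling; the layer equilibrates in ~0.5 s) and require 5 s of
  usable window, both configurable. Segments failing the policy are
  skipped with a warning; implied receptor consumption above 5 % of the
  pool warns that the initial-rate assumption is strained.
* Significant-figure rounding (`round_sig`) is ordinary base-10
  rounding of the mantissa; `paper_rounding` applies it per step as
  described above.

## Limitations

* No coupled reaction–diffusion PDE: transport and kinetics are
  composed, not solved jointly. This is adequate while t₉₀ ≪ the
  observation timescale and conservative otherwise (the
  diffusion-limitation flag marks the regime boundary).
* Single analyte, single protonation step; no activity corrections, no
  thiol oxidation side reactions, no receptor drift or regeneration
  modelling.
* The surrogate-thiol rate constant and the methanol-approximated
  diffusivity enter as user inputs; the package does not endorse or
  correct either approximation.
* The homogeneous-receptor idealization overstates accessibility of
  receptor deep in the porous layer; it is retained because it is what
  makes closed-form kinetics possible and is standard practice.
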