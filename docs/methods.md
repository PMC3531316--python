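# Methods

## The model

`fnfiber` simulates micrometer-scale fibronectin (Fn) fibers as bundles
of independent molecular strands ("nanofibrils") and connects the
simulated strand forces to bulk fiber stresses through a measured
protein concentration.  The model has three layers.

### Entropic elasticity

Each Fn dimer is a worm-like chain (WLC) obeying the Marko–Siggia
interpolation formula

    f(z) = (kB T / A) [ 1/(4 (1 − z/L)²) − 1/4 + z/L ],

with folded contour length `L = 120 nm` and persistence length
`A = 14 nm`.  Temperature defaults to 298 K (`kB T ≈ 4.114 pN nm`);
the experiments the model addresses are room-temperature in vitro
stretches, and the choice of 298 K vs 310 K moves every force by only
~1%.  Both values are configurable.

The inverse law is needed constantly (every equilibration step).
Substituting `u = 1 − z/L` and `φ = f A / kB T` turns the interpolation
formula into the cubic `u³ + (φ − 3/4) u² − 1/4 = 0`, which has exactly
one positive root for every `φ ≥ 0` (one sign change in the coefficient
sequence).  We solve it with a safeguarded Newton iteration started at
`min(1, 0.5/√(φ − 3/4))`, where the iteration is provably monotone, and
switch to the series `z/L = (2/3)φ − (2/9)φ² − (4/81)φ³` below
`φ = 10⁻⁴` to avoid cancellation in `1 − u`.  Round-trip accuracy is
~10⁻¹² relative, far inside the 10⁻⁹ contract, and about two orders of
magnitude faster than bracketed root finding per call — which is why it
was chosen over the more conventional `brentq` approach.

Extensions demanded beyond `z/L = 1 − 10⁻⁹` raise a taut-segment error
instead of silently returning a huge force.

### Stochastic domain unfolding

Each dimer carries 30 unfoldable FnIII domains (15 unique types × 2
copies).  A folded domain under tension `f` unfolds in a time step `dt`
with the Bell-model probability

    p = min(1, k₀ · exp(f Δx / kB T) · dt),

the first-order form standard in Monte-Carlo force spectroscopy; at the
protocol's `dt = 0.73 ms` it agrees with the exponential-survival form
`1 − exp(−k dt)` to O(p²).  On unfolding, the molecule's folded backbone
loses 3.5 nm of contour and a 32 nm strand of unstructured chain
(persistence 0.42 nm) is inserted in series — a net contour gain of
28.5 nm, i.e. 23.75% of the folded dimer contour, with a dramatically
softer force response.  Refolding is not modelled: at the forces and
strains of interest refolding is mechanically suppressed, and omitting
it keeps the trajectory irreversibly bookkept (`total contour =
120 + 28.5 · n_unfolded`, an invariant the tests enforce exactly).

Per-type Bell parameters are read from `src/fnfiber/data/domain_params.yaml`.
Single-molecule rate data exist for only part of the FnIII family, so
the shipped defaults encode the known qualitative hierarchy — zero-force
rates spanning 10⁻⁴ to 3×10⁻² s⁻¹ around the "one event per ~100 s"
scale, rupture lengths 0.38–0.40 nm, FnIII-1 the most stable and
FnIII-2/-9/-10 and the third type among the weakest — and every type
without data aliases FnIII-12.  The file is deliberately plain YAML:
replace rows if you have a calibration.  Because these per-domain values
are a literature-informed default rather than a fitted set, all
force-valued outputs of the stochastic simulation should be read with
tens-of-percent error bars; the deterministic outputs (counts, packing,
geometry) do not depend on them.

Three initial-unfolding presets describe relaxed fibers that already
contain open domains: 0, 4 (four domains carrying FnIII-12 parameters)
or 8 (both copies of FnIII-2, the third type, FnIII-9, FnIII-12) per
molecule.  Preset slack is added with the same bookkeeping as a kinetic
event.

### Fiber architectures and the stretch protocol

Two nanofibril architectures bracket how molecules may share load:

* **equal** — `n` dimers end-to-end; every molecule carries the strand
  tension (default n = 20).
* **disparate** — `n` repeating units in series, each one molecule in
  parallel with two molecules in series (3n molecules).  At a common
  unit span the single-molecule side is proportionally more extended
  and carries most of the unit force, producing two molecular force
  populations.

The fiber starts at `n × z0` with `z0 = 108 nm` (90% of folded contour,
the assumed molecular end-to-end length in a relaxed fiber) and the
boundary separation grows by 0.67 nm per 0.73 ms time step
(0.92 µm/s) up to 473% strain — about 15,250 steps for the default
20-unit fiber.  Each step equilibrates the network, polls every folded
domain once at its molecule's tension, applies all of the step's events
simultaneously, and records.

Equilibration exploits monotonicity rather than generic minimization:
extension-vs-tension is strictly increasing for every series/parallel
WLC assembly, so force balance reduces to scalar root finding (equal)
or a joint Newton iteration on the unit tension and the per-unit force
splits (disparate), warm-started from the previous step and safeguarded
by a bracketed bisection fallback.  This is mathematically equivalent
to minimizing the network strain energy over node positions — a test
checks agreement with a brute-force energy-minimization oracle on a
two-molecule fiber to 10⁻⁴ — but exact and ~10³× faster.  Node force
residuals are tracked and stay below 10⁻⁶ pN at every recorded step.

Randomness comes from one seeded NumPy generator per run; draws are
consumed in fixed (molecule, domain) order, one per domain per step
regardless of folding state, so identical seeds give bitwise-identical
traces and the stream cannot drift with the unfolding history.

## Densitometry

Transmission image pairs (specimen + blank field) at 280/260/220 nm are
converted to base-10 optical density per pixel.  Beer's law
`OD = ε c l(x)` with the amino-acid-composition extinction coefficients
(704975, 412798, 4308680 M⁻¹cm⁻¹) and the cylindrical chord
`l(x) = 2√(r² − x²)` then yields per-pixel dry mass and concentration
maps.  Fibers are pure protein, so the nucleic-acid channel of
two-wavelength UV densitometry is dropped.

Choices where the procedure is genuinely open:

* **Radius and axis**: least-squares fit of the semi-elliptical profile
  `OD(x) ∝ √(r² − x²)` to the length-averaged transverse profile
  (sub-pixel; exact on noiseless synthetic fibers).  A manual override
  is available.
* **Core region**: concentration statistics are averaged over
  `|x| ≤ 0.5 r` (configurable) to avoid rim pixels where `l(x) → 0`
  amplifies noise and the circular-cross-section assumption is weakest;
  pixels with `l` below 10% of the diameter are masked outright.
* **Molar ↔ mass conversion**: molecular mass defaults to 500 kDa
  (dimeric Fn); substitute a sequence-derived value via the `mw`
  options if desired.

The synthetic image generator emits `I = I₀·10^(−εcl(x))` with optional
Gaussian blur (~240 nm effective resolution), multiplicative intensity
noise, and Poisson counting noise.  It reproduces the geometry and the
Beer-law physics of the instrument but not its optical artifacts
(interference fringes, flat-field errors, focus drift), so passing the
recovery tests demonstrates correctness of the inversion, not
robustness to every real-world artifact.

## The scaling bridge

With concentration `c`, fiber diameter `d₀` and molecular mass `MW`,
the number of molecules in cross-section is

    N_cs = (c N_A / MW) · (π d₀²/4) · z0 ,

because each strand occupies one end-to-end length `z0` of axial repeat.
Equal-loading fibers have `N_cs` strands; disparate fibers `N_cs/3`
units.  Simulated tensions scale to fiber force by the strand count and
to stress via the constant-volume cross-section `A(ε) = A₀/(1+ε)`
(equivalently `d(ε) = d₀/√(1+ε)`), an assumption supported by measured
diameter reductions under stretch.  The same numbers give packing
estimates: `A(ε)/N_cs` is the cross-sectional area available per
molecule, and with a 7–10 nm² occupied molecular footprint the solute
fraction is `1 − occupied/available`.

Running the bridge backwards, a measured fiber force trace divided by
the strand count estimates per-molecule forces; for disparate fibers
the unit force is split between the two populations preserving the
single:pair tension ratio of a companion simulation at matched strain
(matched strain, not matched unit force — the two readings of the
procedure differ only where the ratio varies quickly, and matched
strain is the direct reading).  The `z0` scan evaluates, per assumed
`z0`, the experiment-scaled molecular force `F(ε_ref)/N_cs(z0)`
(decreasing in `z0`) against the simulated molecular force at the
remapped span `z0·(1+ε_ref)` (increasing), reporting the crossing by
linear interpolation; reference strain defaults to 300%.

The external in vitro force trace the original comparison used is not
redistributable, so a synthetic generator
(`make_synthetic_measured_trace`) produces deterministic model-generated
traces with optional noise; the estimation and scan operations are
validated by round trip (a trace generated at `z0*` scans back to
`z0*`; equal-loading estimation recovers the injected molecular curve
exactly).  Published endpoint values that depend on that external trace
are therefore not asserted anywhere.

## Problem sizes and numerical settings

* Full-protocol simulations (20 units, 473% strain) are used for the
  stress figures: ~15,250 steps, seconds (equal) to ~20 s (disparate)
  per run; stochastic acceptance figures average 10 seeds.
* Property checks that probe orderings rather than magnitudes (preset
  softening, architecture comparison) run 5-unit fibers over 6–20
  seeds; these properties are per-strand and do not depend on the
  number of units.
* Equilibrium tolerance: extension residuals to 10⁻¹³ relative,
  giving force residuals ≤10⁻⁶ pN with large margin.
* Degenerate inputs: zero extension → zero tension everywhere;
  extension beyond the available contour raises a taut-fiber error
  (CLI exit code 3); an unfoldable-domain-free molecule polls to an
  empty event list.

## Known limitations

* Per-domain Bell parameters are defaults, not fits; stochastic stress
  outputs carry correspondingly wide uncertainty.
* No refolding, no steric or viscous inter-fibril coupling, no fiber
  failure criterion, and a strictly uniaxial geometry.
* The densitometry module assumes the fiber axis is parallel to the
  image rows and the cross-section circular; rotate or re-fit real
  images first.
* Equal/disparate are two points in the space of load-sharing
  architectures; real fibers likely mix them.
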