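# Methods

## Reflectivity model

Samples are slab models: contiguous homogeneous layers between a
semi-infinite incident medium and a semi-infinite backing medium. The
specular reflectance is computed exactly with the Abelès transfer-matrix
formalism; the test suite carries an independently coded Parratt
recursion and the two agree to 1e-10 relative on randomized stacks (the
two algorithms are algebraically equivalent, so this is a strong check
on the implementation, not on the physics).

Conventions, chosen to match the mainstream NR analysis packages:

* **Roughness** — Nevot–Croce Gaussian factors
  exp(−2 k_j k_{j+1} σ²) on each interfacial Fresnel coefficient.
  `Layer.roughness` refers to the interface with the medium above the
  layer; the substrate interface roughness lives on the `Sample`.
* **Hydration** — linear volume-fraction mixing,
  ρ_eff = (1−h)·ρ + h·ρ_solvent. For polarized channels the magnetic
  SLD offset is applied to the material before mixing (the solvent
  carries no moment).
* **Resolution** — constant dQ/Q Gaussian smearing with dQ/Q read as
  the FWHM (default 2 %). The convolution uses a fixed 17-node
  Gauss–Legendre rule over ±3.5σ with weights renormalized to unit sum,
  so constants are conserved exactly. Away from the critical-edge kink
  the rule agrees with 501-point dense quadrature to better than 1e-6
  relative; at the kink itself any fixed rule differs from dense
  quadrature at the few-1e-4 level, which is far below counting noise
  in any simulated dataset.
* **Background** — added after smearing and scaling:
  R_tot = scale·smear(|r|²) + background. Data are synthesized without
  background subtraction; the background is a model parameter, which
  keeps the counting statistics Poisson. Background-subtracted
  (Skellam-statistics) data are deliberately unsupported.
* **Units** — user-facing SLDs are in 1e-6 Å⁻² and converted to Å⁻²
  once, inside the kernel. Lengths in Å, angles in degrees, times in
  seconds.
* Spin-up/down non-spin-flip channels use nuclear ± magnetic SLD per
  layer. Spin-flip scattering and energy-dependent SLDs are out of
  scope. An imaginary SLD slot exists in the kernel but defaults to 0.

## Instrument model and counting statistics

A time-of-flight white-beam instrument measures one Q point per
wavelength at fixed angle. The instrument is characterized by an
incident flux table (neutrons/s per wavelength bin) at a reference angle
θ_ref = 0.3°; the 60 mm constant footprint is absorbed into the profile
normalization. Opening both collimation apertures linearly with angle
keeps the footprint constant and scales the flux by (θ/θ_ref)² — only
this ratio law matters to any result.

Q bins are log-spaced over the band (100 per angle by default), each
mapping back to a unique wavelength sub-interval; the incident counts in
a bin are the integral of the (piecewise-constant) flux density over
that sub-interval, times the angle factor and the counting time.
Expected counts are λ_k = R_tot(Q_k)·incident_k; noisy realizations are
Poisson draws with r = n/incident and dr = √n/incident. Zero-count bins
are kept, with dr set by a single-count floor so log-scale fitting
remains possible. Absolute eigenvalue magnitudes depend on the per-bin
incident normalization; all design comparisons use ratios, which do
not.

The bundled synthetic flux generator emulates a 1–14 Å white beam with a
Maxwellian-like spectrum, φ(λ) ∝ λ⁻⁵ exp(−(λ_T/λ)²), λ_T = 4 Å (peak
near 2.5 Å), normalized to 5e5 neutrons/s over the band at θ_ref — a
realistic order of magnitude for a medium-resolution spallation-source
reflectometer, giving 1e5–1e7 counts in low-Q bins for minutes-long
measurements. The polarized variant multiplies the spectrum by a smooth
polarizer transmission (5 % floor, sigmoid cut-on at 3.5 Å) because
polarizing optics suppress short wavelengths; its integral is therefore
below the nominal rate. What the generator does **not** emulate:
measured spectral structure of a real guide, gravity and chopper
effects, angle-dependent backgrounds, or detector efficiency. Passing
tests therefore demonstrate the statistical machinery and the relative
design comparisons, not agreement with any specific beamline's absolute
eigenvalues; a measured two-column flux table drops in via
`load_flux` to specialize results to a real instrument.

## Fisher information

For independent Poisson bins,
G_ij = Σ_k λ_k⁻¹ (∂λ_k/∂θ_i)(∂λ_k/∂θ_j); bins with λ_k = 0 contribute
zero (the well-defined limit), never NaN. Gradients are central finite
differences with relative step 1e-3 of the parameter value (absolute
floor 1e-8); a step-halving test keeps the choice honest on every
bundled model, and all stencil points are evaluated in one vectorized
batch of the Abelès kernel. The matrix is symmetrized against round-off
and eigen-decomposed with a symmetric solver; eigenvalue ties need no
special handling since only the value enters the objective.

Importance scaling multiplies G by D = diag(w_i) on both sides. The
default w_i = |θ_i| expresses equal importance per *fractional* change,
making eigenvalues dimensionless and comparable across mixed units
(thicknesses in Å next to hydrations in [0,1]); any positive custom
weighting can be set per parameter. A Monte-Carlo oracle (the observed
information averaged over 5 000 simulated datasets) reproduces G to a
few percent — the residual is Monte-Carlo and finite-difference noise,
which is why the tests assert a few-percent band rather than machine
precision.

Cramér–Rao bounds: per-parameter σ_i from the inverse matrix diagonal
(native units from the raw matrix, fractional from the scaled one);
worst-combination bound λ_min^(−1/2). Because G is exactly linear in
counting time, time ×100 scales every eigenvalue ×100 and divides the
worst-combination bound by exactly 10. At high counts the bounds agree
with brute-force grid posteriors within 15 %.

For kinetic series (a monolayer degrading while measured once per
snapshot) only the tracked parameter is informative; the scalar FI is
summed over snapshots, quantifying the maximum information about that
parameter over the full experiment.

## Sample models

Structural defaults in the sample zoo are literature-typical synthetic
placeholders (PC-like bilayer on silicon, DPPG-like monolayer, YIG/Pt
stack) — every value is overridable, and the supported surface is the
models' *design-search behaviour*, which is robust to the placeholder
values: endpoint contrasts optimal for two-contrast bilayer
measurements, null-reflecting water optimal for monolayer APM kinetics,
Pt-cap thickness (not YIG thickness) controlling induced-moment
sensitivity. Deuteration swaps scattering lengths only; molecular
volumes are held fixed, so the solvent contrast re-mixes hydrated
layers without touching the structure.

Underlayers (deposited films between the native oxide and the bilayer)
carry fixed 2 Å roughness and 0 % hydration; when present, the oxide
hydration is pinned to 0 and the oxide hydration and oxide/bilayer
roughness parameters leave the FI parameter set — underlayers are
nuisance quantities, well characterized before deposition, and are
never part of the information objective.

The magnetic stack fixes the magnetized Pt sub-slab at 21 Å adjacent to
the YIG regardless of cap thickness, so thickening the cap never adds
total moment. The moment↔magnetic-SLD conversion uses the standard
2.699e-5 Å per μB coupling (validated against bulk iron in the tests);
the default induced magnetic SLD is 0.0164e-6 Å⁻², i.e. roughly
0.009 μB per Pt atom at 0.0662 atoms/Å³.

Kinetic series spacing is linear in APM with equal time per snapshot
(20 snapshots over 54.1–500 Å², 150 min total by default).

## Design search

Landscapes and optimization objectives use noise-free expected counts —
the exact limit of the "large time budget" device for suppressing
simulation noise — so every landscape is deterministic and
bit-reproducible. Poisson realizations are used only for validation
datasets. All contrasts share the same angles and the same angle-time
proportions (default 0.7°/2.3°, 15:60 split); time splits are
renormalized non-negative weights on the simplex, and rescaling the
total budget multiplies every eigenvalue by the same factor, leaving
all argmaxes unchanged.

Differential evolution defaults: best/1/bin, population 15×dim,
tol 0.01, maxiter 200, polish on, explicit seed; non-finite objectives
are penalized, not fatal. Near-duplicate contrasts (within
0.05e-6 Å⁻²) are reported merged with summed time fractions. Angle
optimization holds the contrasts fixed at D2O + H2O unless a fully
joint search is requested. Time penalties for changing contrast or
angle are not modelled.

## Likelihood validation

The Gaussian log-likelihood −½ Σ [(R_i − R_model(Q_i))/δR_i]² omits its
additive normalization constant (it cancels in every ratio used). Model
discrimination simulates data from the moment model over both
non-spin-flip channels (times are per measured spin state) and tracks
the mean log likelihood-ratio versus time; a brute-force two-parameter
grid posterior with flat priors stands in for nested sampling as the
ground truth for uncertainty cross-checks, warning when more than 1 %
of the mass sits on the grid boundary.

## Problem sizes and numerical choices

Default problem sizes used throughout the tests and the acceptance
script, chosen as the smallest sizes at which every check is stable:
100 Q points per angle (40–60 in pure property tests), 100-bin flux
tables, 50-point contrast grids, 20-snapshot kinetic series, 5 000
Monte-Carlo datasets for the information oracle, 40–50 replicates for
likelihood-ratio curves, and 45×45 posterior grids sized at ±6 CRB σ.
The two-contrast design search runs the DE defaults above and typically
converges in ~30 generations.

## Known limitations

* Absolute eigenvalues depend on the synthetic flux normalization and
  the placeholder sample parameters; only relative comparisons between
  designs are meaningful, and published per-system eigenvalue tables
  cannot be reproduced without the instrument's measured flux profile
  and the originally fitted model parameters.
* The Poisson FI does not apply to background-subtracted data.
* Monolayer and bilayer models are hydration-mixed slabs; lateral
  defect structure and asymmetric-leaflet microstructure beyond
  hydration fractions are not modelled.
* The smearing kernel assumes constant dQ/Q; wavelength-dependent
  resolution would need a per-point kernel.
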