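# Methods

This note documents the models inside `seedchar`, the choices that were
genuinely open, and what the test suite does and does not demonstrate.

## Seed geometry

The seed is a surface of revolution about z (origin at the seed centre,
polar angle θ from the long axis, so θ₀ = 90° is the transverse plane).
Regions partition space: silver marker (cylinder, 3.25 × 0.50 mm,
10.53 g/cm³), radioactive coating (0.5 µm shell on the marker surface,
treated as a massless emission locus), vacuum gap, titanium capsule wall
(4.5 mm long, 0.8 mm outer diameter, 0.06 mm wall, 4.5 g/cm³), exterior.
The end welds are hemispherical shells of 0.5 mm outer radius and wall
thickness; because the stated weld radius exceeds the 0.4 mm tube radius,
the capsule outer solid is the union of the tube and two end balls — a
slight weld bulge, retained as-is since nothing finer is specified.  The
gap fill is vacuum; at these energies air in the gap would be
indistinguishable.

Emission samples the coating surface uniformly by area (lateral surface
plus, by default, the rod end faces — switchable with
`SeedModel(coat_end_faces=False)` since the coverage of the end faces is
not documented) with isotropic directions and energies from the five-line
¹²⁵I spectrum: 27.2 (27.5%), 27.5 (51.3%), 31.0 (13.7%), 31.7 (3.0%),
35.5 keV (4.5%).

Ray tracing uses the candidate-surface method: all positive intersections
with the primitive cylinders, planes and spheres are collected and the
nearest one that changes the region classification is the boundary.  A
second named configuration (`model-6711`: 3.0 mm rod, 0.05 mm wall) is
bundled for benchmarking and not exercised by default.

## Photon physics

Analog transport between 5 and 40 keV with an energy cutoff δ = 5 keV —
the cutoff deliberately swallows titanium K x-rays (~4.5 keV), which is the
standard convention for these sources.  Channels at each interaction:

- **Photoelectric**: terminates the history, except in silver above the
  25.514 keV K edge, where one 22.1 keV K x-ray is emitted isotropically
  with yield 0.83.  Escaping fluorescence measurably shapes the spectrum of
  silver-marker seeds.
- **Incoherent**: free-electron Klein–Nishina differential sampling
  (rejection on the exact KN kernel), no S(q,Z) shape correction.
- **Coherent**: Thomson kernel modulated by a screened form factor
  F(q,Z) = Z/(1+(αs)²)², α ∝ E·Z^(−1/3), screening scale normalised so the
  integrated Rayleigh cross-sections match tabulated magnitudes near
  30 keV; direction change only.

No electron transport: collision kerma is scored as dose (CSDA ranges of
≤35.5 keV electrons are tens of µm, far below every cell size).

**Cross-section data.**  Total µ/ρ and µ_en/ρ for water, PMMA, dry air,
titanium and silver are vendored in-code on a coarse 5–40 keV grid
(standard-compilation values, transcription fidelity ~1–2%), with a double
point bracketing the silver K edge.  Interpolation is log-log monotone
piecewise-cubic per segment — a straight log-log chord across the sparse
20→30 keV interval would overestimate attenuation at the emission lines by
~3%.  The channel split is constructed at load time: coherent from the
form-factor integral; photoelectric for the low-Z media inferred from
µ_en via the energy balance µ_en = µ_pe + µ_incoh·f_C(E) (f_C the analytic
KN mean energy-transfer fraction), which makes the incoherent remainder
carry the compilation's electron-binding suppression; for Ti and Ag
(fluorescence escape breaks that balance) incoherent is free-KN × Z/A and
photoelectric the remainder.  Totals and µ_en — the quantities that drive
free paths and scoring — are always the vendored values exactly.

## Tallies

Scoring cells are full azimuthal rings: a thin spherical shell (default
±0.5 mm) around each scoring radius cut by polar cones around each angle.
Under axisymmetry this is exact and raises the per-history scoring mass by
~10³–10⁵ over mm-scale voxels, which is what makes 10⁶-history desk runs
match the statistical quality that point-detector codes need 10⁹ histories
for.  The estimator is track-length collision kerma
(Σ ℓ·E·(µ_en/ρ)/V_cell); variance is accumulated history by history, and
the relative standard error is reported per cell.  Within a shell crossing,
polar-bin assignment subdivides the chord midpoints at 0.2 mm; the residual
binning bias is second-order in the substep.

Air-kerma strength places the seed in a 15 cm vacuum sphere and scores an
air-response ring at 10 cm, ±1° around the transverse plane (the ring
equivalent of a small transverse voxel); S_k = K·d².  With the dose tally
in keV/g and S_k in keV·cm²/g per emitted photon, Λ = D/S_k is numerically
in cGy·h⁻¹·U⁻¹ (1 cGy per µGy·m² = 1 cm⁻²) and the emission normalisation
cancels, so the absolute source activity never enters.

Two transport routes exist on purpose: a per-photon pure-Python
implementation returning explicit track segments (`transport_photon` +
`score_kerma`) and the production numba kernel.  They share only the data
tables; a 3σ statistical cross-check in the suite compares them on a point
source in water.  The kernel is single-threaded and explicitly seeded:
identical seeds give bit-identical tallies.

## TG-43 extraction

g(r) and F(r,θ) follow their defining ratios with the line-source geometry
function (θ = 0 uses the standard long-axis limit 1/(r² − L²/4); the
point-source limit 1/r² is used for L = 0).  Normalisations g(r₀) = 1 and
F(r, 90°) = 1 hold exactly by construction.  Polynomial fits (quintic,
unweighted least squares — no weighting scheme is documented for such
fits, and residual diagnostics are returned so the choice is auditable)
use r in cm for g and θ in radians for F; published per-radius anisotropy
coefficients could not be reproduced under any sign/unit convention we
tried, so only the intercept p₀ ≈ F(r, 0°) is compared.  Reconstruction
interpolates bilinearly in (r, θ) for F, via the fitted polynomial for g
when coefficients exist (log-linear in r otherwise), and refuses
extrapolation unless asked.

PMMA→water conversion factors P_phant(r,θ) are element-wise ratios of
matched water and PMMA tallies with errors combined in quadrature.  Note
their behaviour with the vendored data: the factor is dominated by the
µ_en ratio (water/PMMA ≈ 1.6 at these energies) and *decreases* slowly
with r because liquid water is actually more attenuating per cm than PMMA
at 27–31 keV (0.43 vs 0.40 cm⁻¹) — density intuition misleads here.  The
factor cancels identically in the synthetic round trip, so its absolute
scale does not touch parameter recovery.

## Synthetic TLD campaign

The generator emulates six seeds (labelled strengths 1.041, 1.016, 0.995,
0.991, 0.901, 0.860 mCi; bridge 1 mCi = 1.270 U; decay with T½ = 59.4 d
integrated over the exposure) measured in two PMMA phantoms: Phantom I
(transverse plane, radii 0.5, 0.7, 1–10 cm step 0.5, azimuth every 5°) for
Λ and g(r); Phantom II (polar grid, radii 0.5–7 cm, polar angles 0–350°
step 10°, except the 0.5 cm ring at 20° steps offset to include 90°) for
F.  A reading is the true PMMA dose (TG-43 reconstruction of the truth
dataset divided by P_phant) through a linear calibration (dose = slope ×
light, valid below 10 Gy — readings above the bound raise a saturation
error) and the LiF-in-PMMA energy response (1.14 at the measurement
quality vs 1.17 at the 48 keV calibration quality; the net factor divides
back out in analysis).

Noise model (percent magnitudes are the campaign's standard budget):

- repetitive reading scatter — lognormal, CV 4.5%, independent per reading;
- positioning — radial hole jitter with σ chosen so the dose effect at
  1 cm is 3.5% (σ = 0.0175 cm); drawn **once per hole per campaign**,
  because holes are machined once and shared by all six seeds.  Jitter on
  an r⁻²-like field makes disagreement grow toward the source, worst at
  0.5 cm, as observed in real campaigns;
- calibration (2.6%), seed-strength (3.0%) and PMMA→water (3.0%)
  systematics — one lognormal factor each per campaign.

The default exposure is 48 h: long enough for good light yield, short
against the half-life, and keeping the largest dose (~3 Gy at 0.5 cm for
~1 mCi) below the 10 Gy linearity bound.  This default is the package's
own choice; real exposure protocols are rarely published.

The analysis chain is the exact inverse of the generation chain (decay
correction, calibration, energy response, per-seed strength normalisation,
seed averaging, P_phant, supplementary-angle folding, TG-43 ratios), so a
noiseless campaign inverts to machine precision — this is asserted in the
suite.  Λ is taken from the designated reference hole (lowest azimuth at
r₀) rather than the 72-hole azimuthal mean: the standard budget counts
positioning and repetitive scatter as full-size components of %u_Λ, which
matches a single reference-hole chain; ring means would average them away.
g(r) does use the ring means.  Supplementary-angle folding averages each
angle with its three mirror images {180−θ, 180+θ, 360−θ} (the seed is
mirror-symmetric, so both readings of "supplementary" coincide after
folding); the fold is idempotent and skips missing holes, recording counts.

Dosimeter volume averaging (5 sample points along the 6 mm rod axis) is
available via `rod_axis_points` but off by default: uncorrected volume
averaging biases Λ by about −4% at r₀, which would defeat the exact
noiseless inversion, and point treatment of TLDs is the campaign
convention.  Neighbour-dosimeter shadowing is not modelled (for F it
cancels by the normalising ratio; for Λ it is part of the positioning
budget).

With these magnitudes the replicate SD of recovered Λ is ≈ 6.5%,
consistent with the 7.6% quadrature total (repetitive scatter averages
over six seeds; the rest is campaign-systematic), and the bias is < 0.1%.

## Uncertainty budgets

Components are relative standard uncertainties in percent, combined in
quadrature with no covariance; totals are reported at one decimal,
half-up, full precision kept internally.  The two standard budgets ship as
constructors: experimental {3.0, 3.5, 2.6, 3.0, 4.5} → 7.6% and Monte
Carlo {3.2, 3.5, 1.5, 2.0, 0.2, 0.5} → 5.4%.  The MC budget lists a
positioning term, unusual for a pure simulation — it is reproduced as
published.  %u_Λ combines the reference-point dose and S_k uncertainties
in quadrature.  No coverage-factor expansion is applied.

## Problem sizes and accuracy envelope

Default runs use 2×10⁶ histories for S_k and 5×10⁶ for dose tables
(seconds to ~1 min on one CPU with the ring tallies); the acceptance
script uses 2×10⁶ per arm.  At those sizes the transverse relative error
is ~0.5% at 1 cm and stays below 2.5% at 10 cm.

Against the published characterization of this seed: the simulated g(r)
tracks the published quintic within ±5% over 0.5–10 cm, and F(1 cm, θ)
matches the published column to ≈0.03 mean absolute deviation for
θ ≥ 30°.  Λ comes out at ≈ 0.925 ± 0.010 (2×10⁶ histories) — inside the
5.4% MC budget around the published MCNP5 value 0.975 and within 2% of
the published measured value 0.943.  The residual few-percent offset from
the MCNP5 number is the expected signature of the simplified physics and
independent data tables (channel construction, free-KN angular shapes, no
S(q,Z), transcribed µ grids); it was characterised, not calibrated away.
F below ~20–30° runs high because the end welds are modelled as thin
shells — small-angle anisotropy is known to be dominated by the
(undocumented) weld-bead mass, and real measurements disagree with
simulations worst exactly there.

## What the synthetic tests do not show

The TLD arm's parameter recovery demonstrates that the analysis chain is
unbiased and that the noise budget propagates as designed; it cannot
validate the physical noise magnitudes themselves (they are inputs), nor
real-detector effects absent from the generator: glow-curve kinetics,
fading and annealing history, reader drift, batch inhomogeneity, and
inter-dosimeter shadowing.  Likewise the transport oracles (attenuation,
inverse square, Klein–Nishina moments, two-route consistency) validate
the code against its own vendored data, not the data against nature.
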