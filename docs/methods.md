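# Methods

## Model overview

`brachymc` computes absorbed dose around an encapsulated ¹⁹²Ir HDR source
under the collision-kerma approximation: secondary electrons are assumed to
deposit their energy where they are set in motion, so dose equals collision
kerma everywhere (the F6-tally convention of MCNP-family codes). This is
accurate wherever charged-particle equilibrium holds, i.e. beyond a few
electron ranges (≲1 mm in unit-density tissue at ¹⁹²Ir energies, ~4 mm in
inflated lung) from the capsule and from media interfaces; no electron or
beta transport is attempted.

Photon transport is fully analog. A history starts uniformly distributed in
the active core volume with an isotropic direction and a line energy drawn
from the bundled spectrum. Inside the source the ray is traced through the
iridium core and steel capsule/cable segments and an exponential optical
depth decides whether it interacts there (photoelectric absorption kills
the history; Klein–Nishina incoherent or Thomson-law coherent scattering
redirects it, and the trace repeats) or escapes into the phantom. In the
homogeneous phantom, free paths are sampled from the local total
attenuation coefficient, the interaction channel proportionally to the
partial coefficients, and photons are discarded on leaving the phantom or
falling below the 5 keV cutoff (the spectrum floor is 8.9 keV, so the
cutoff only acts after multiple scatters). Once a photon has left the
convex capsule envelope the capsule is no longer modelled; re-entry of
scattered photons into the 1.1 mm-diameter capsule is a sub-0.1 % effect at
every tally radius used.

## Source geometry

Active core: length 0.35 cm, radius 0.03 cm, iridium at 22.42 g/cm³.
Capsule: AISI 316L stainless steel (Fe 0.655, Cr 0.17, Ni 0.12, Mo 0.025,
Mn 0.02, Si 0.01; 8.0 g/cm³), outer radius 0.055 cm. Only the core
diameter and the capsule outer diameter are well determined for this
source, so the full 0.025 cm radial gap is modelled as solid steel with a
flat 0.025 cm distal end cap and no air gap — the simplest geometry
consistent with the published dimensions. Capsule detail mainly perturbs
the anisotropy function within ~10° of the poles. On the proximal side a
solid-steel drive-cable stub of the capsule radius extends exactly 0.2 cm
beyond the cap; beyond it the world is phantom medium.

The proximal (cable) pole carries ~0.2 cm more steel than the distal tip,
so the dose is visibly lower there. Published anisotropy tables for this
source put the *lower*-valued pole at θ = 0°, which therefore must be the
cable side; tally grids default to that orientation (θ = 0 ≡ cable) and
accept `theta_zero="tip"` to flip it.

## Interaction coefficients

Per-element mass attenuation and mass energy-absorption coefficients are
bundled as CSV fixtures on a shared ~70-point log grid from 5 keV to
1.5 MeV (with points hugging each K-edge in range), regenerated by
`scripts/make_physics_fixtures.py`:

* **Incoherent**: exact free-electron Klein–Nishina total cross section,
  Z electrons per atom. Binding (incoherent-function) corrections are
  omitted; they are a <1 % effect above 50 keV, where almost all ¹⁹²Ir
  kerma originates. The incoherent part of μ_en uses the Klein–Nishina
  energy-transfer moment evaluated by Gauss–Legendre quadrature.
* **Coherent**: Thomson differential cross section weighted by a
  one-parameter screened form factor `F(q,Z) = Z/(1+(a_s q)²)²` with
  Thomas–Fermi scaling `a_s ∝ Z^(-1/3)`, integrated numerically.
* **Photoelectric**: piecewise power laws in energy anchored per Z-family
  (low-Z scaled from an oxygen anchor with an energy-dependent Z exponent,
  transition metals from an iron anchor set, heavy elements from a
  lead-like anchor set scaled by Z^4.6 with an explicit K-edge jump). The
  photoelectric part of μ_en subtracts mean K-fluorescence escape;
  radiative (bremsstrahlung) losses are neglected, a <0.5 % effect below
  1 MeV in low-Z media.

The two free constants (oxygen photoelectric scale, coherent screening
length) are fit once to standard compiled water attenuation values at
30–100 keV and then frozen. Validation against independent water and air
checkpoints (bundled in `data/reference/photon_coefficient_checkpoints.csv`
and asserted in the test suite) shows agreement within 0.3 % for μ/ρ and
μ_en/ρ above 50 keV and within ~1 % at 30 keV; cortical bone, iron and
iridium totals land within ~3 % of standard compilations. Compound tables
are mass-fraction mixtures of the elemental fixtures scaled by density;
all lookups are log-log interpolated, exact at grid nodes, with
extrapolation refused. Tissue compositions follow ICRU-44; dry air is the
standard C/N/O/Ar mixture at 1.205 mg/cm³.

The ¹⁹²Ir spectrum fixture lists 28 lines from 0.0089 to 1.0615 MeV
(≈2.34 photons per decay, mean 0.349 MeV): the β⁻/EC gamma lines plus Pt/Os
K and L fluorescence. Decay-data snapshots differ at the percent level in
total yield; since every extracted quantity is a per-history *ratio*, such
differences cancel and only the line energy distribution matters.

## Tallies and uncertainties

All phantoms are axisymmetric about the source axis, so tallies are full
azimuthal rings: thin transverse rings (θ = 90° ± 2.5°) for radial
profiles, (r,θ) ring maps for the anisotropy function, full spherical
shells for the analytic oracles, and a cylindrical (ρ,z) pixel grid for the
2-D matrices. Radial half-widths are 0.25 mm for r ≤ 1 cm, 0.5 mm to 5 cm
and 1 mm beyond; polar half-widths 0.5° within 10° of the poles and 2.5°
elsewhere — chosen to keep volume-averaging bias below ~0.5 % at the
innermost tabulated radius. Rings centred on the phantom surface (the 15 cm
row of the 30 cm-sphere tables) are clipped to the interior and normalised
by in-phantom volume, otherwise the estimator would halve the boundary bin.

Kerma is scored with a track-length estimator: each flight segment adds
`E·(μ_en/ρ)(E)·chord/V` to every ring it crosses (exact sphere-interval
chords; the polar bin of a sub-chord is classified at its midpoint, exact
in the thin-ring limit). Histories are processed in 40 equal batches; the
quoted 1σ relative error is the batch-mean standard error, verified to
scale as 1/√N. Runs are bit-reproducible for a given seed and batch count.

Air-kerma strength uses a vacuum world with air-scoring rings (±1° about
the transverse plane, ±0.5 cm radially) at 50 and 100 cm; `K·d²` must agree
between the two distances within 3σ — a built-in inverse-square check that
raises on geometry bugs — and their inverse-variance mean is S_K. Because
numerator and denominator share the same per-history normalisation, Λ and
all dose ratios are independent of the spectrum's absolute yield.

## Problem sizes

Reference-quality runs for tables of this kind use ≥10⁸ histories; the
desk-scale defaults here are 5×10⁶ per medium for the canned experiments
and 10⁷ (water, bone) / 5×10⁶ (lung) in `scripts/acceptance.py`, giving
≲1 % 1σ on transverse rings out to 15 cm and a few % at the narrow
(1 cm, 1°) polar ring. The `--full` CLI flag restores 10⁸. The test suite
runs reduced versions (≈2×10⁶ per medium) and widens its stochastic
tolerances with the actual run errors, so the checks remain
statistically fair at any scale.

## Synthetic fields and what they do (not) show

`brachymc.fields` provides closed-form stand-ins for transport output: an
attenuated point-source field, a TG-43 composite `Λ·G_L·g₀·F₀` field, and
constant-coefficient toy worlds (pure absorber, zero-attenuation,
everything-absorbed). They are deterministic, noise-free and share the
`TallyResult` shape, so the extraction stage cannot distinguish them from
real tallies. Round-tripping the composite through extraction recovers its
inputs to 10⁻¹⁰, which validates the geometry-function algebra and
normalisation conventions — but says nothing about transport physics; that
is covered separately by the analytic-oracle transport tests and the
comparisons against published tables. No Monte Carlo noise is emulated.

## Numerical choices

* Compton sampling: rejection on the energy fraction x = E′/E against
  `h(x) = x + 1/x − 1 + cos²θ(x)` bounded by its value at x_min
  (~50–70 % efficiency over the ¹⁹²Ir range); the sampled angle follows
  from Compton kinematics, so energy–angle consistency is exact.
* Coherent sampling uses the plain Thomson angular law (no form-factor
  sharpening) while coherent attenuation uses the form-factor-integrated
  cross section — consistent totals, slightly too-wide coherent angles;
  since coherent scattering neither transfers energy nor (at these
  energies) dominates, the effect on kerma is well below the quoted
  statistics.
* Geometry function: β is evaluated with `atan2`, continuous through both
  poles; on-axis points inside the active length (r ≤ L/2, θ = 0) are
  rejected. For point-source limits use L ≈ 10⁻⁴ cm; far smaller L values
  lose precision to cancellation in β.
* g(1 cm) and F(r, 90°) are set to exactly 1 after division (their
  relative errors are zeroed) so normalisation identities hold bitwise.

## Known limitations

* No electron transport: within ~1 mm of the capsule (further in lung) the
  kerma approximation overestimates true dose; identical in kind to any
  F6-style calculation.
* Heterogeneous (voxelised) phantoms, applicators and dwell sequences are
  out of scope; phantoms are single-medium spheres or cylinders.
* The photoelectric parameterization is calibrated for dosimetric accuracy
  in tissue-like media over 30 keV–1.5 MeV; below ~20 keV in high-Z media
  it is only qualitatively correct (photons there are absorbed within the
  source regardless).
* The bundled published reference tables for the lung phantom embed a
  lung-to-water normalisation (Λ_lung/Λ_water ≈ 0.88) that collision-kerma
  physics does not reproduce: with per-history kerma ratios, the ~10 %
  lower attenuation over the first centimetre of 0.26 g/cm³ lung almost
  exactly offsets its missing scatter build-up, giving
  D_lung/D_water ≈ 0.98 at 1 cm and Λ_lung ≈ 1.10 — while the same
  pipeline reproduces the reference water and bone dose-rate constants to
  0.3 % and every radial-dose-function column (including lung) to <2 %.
  The package reports its computed lung values; the corresponding
  reproduction-layer tests against the reference lung ratios fail by
  construction and are left failing rather than renormalised.
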