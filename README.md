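# brachymc

Analog Monte Carlo photon transport with collision-kerma scoring and AAPM
TG-43 parameter extraction for the Nucletron microSelectron HDR ¹⁹²Ir
brachytherapy source, in water and in non-water tissues — ICRU-44 cortical
bone (1.92 g/cm³) and inflated lung (0.26 g/cm³).

HDR treatment planning conventionally assumes a water environment, but
tumours sit next to (or inside) bone and lung, whose densities differ from
water by factors of ~2 and ~4. `brachymc` quantifies what that does to the
delivered dose: it simulates the encapsulated source (0.35 cm × 0.06 cm
iridium core, AISI 316L capsule and 2 mm drive-cable stub) centred in
homogeneous phantoms and extracts the TG-43 quantities

- air-kerma strength **S_K** (vacuum world, transverse air-kerma ring
  tallies at 50 and 100 cm, `S_K = K_air(d)·d²`),
- dose-rate constant **Λ = Ḋ(1 cm, 90°)/S_K**,
- radial dose function **g(r) = [D(r)/D(1)]·[G_L(1,90°)/G_L(r,90°)]**,
- anisotropy function **F(r,θ) = [D(r,θ)/D(r,90°)]·[G_L(r,90°)/G_L(r,θ)]**,

with the TG-43 line-source geometry function `G_L(r,θ) = β/(L·r·sinθ)`
(on-axis limit `1/(r² − L²/4)`, L = 0.35 cm), plus medium/water dose-ratio
curves, a phantom-size study, and 2-D cylindrical dose matrices.

Transport is the collision-kerma analogue of an MCNP F6 run: analog photon
tracking (Klein–Nishina incoherent scattering, Thomson-law coherent
redirection, photoelectric absorption, 5 keV cutoff), charged-particle
equilibrium assumed, and kerma accumulated with a track-length estimator on
azimuthal-ring tallies so dose = collision kerma everywhere. Interaction
coefficients come from bundled per-element tables (5 keV–1.5 MeV) combined
by the mass-fraction mixture rule; the ¹⁹²Ir line spectrum
(0.0089–1.0615 MeV, ≈2.34 photons/decay) ships as a fixture. See
`docs/methods.md` for the physics model, its assumptions and limits.

## Worked example

```python
import brachymc as b

phantom = b.PhantomSpec(shape="sphere", diameter=30.0,
                        medium=b.load_material("water"))
rings = b.transverse_rings([1.0, 2.0, 5.0, 10.0, 15.0], clip_radius=15.0)
(profile,) = b.run_transport(b.SourceGeometry(), b.ir192_spectrum(), phantom,
                             [rings], n_histories=1_000_000, seed=42)
s_k, _ = b.compute_air_kerma_strength(b.SourceGeometry(), b.ir192_spectrum(),
                                      n_histories=500_000, seed=43)
print(f"dose-rate constant: {b.dose_rate_constant(profile.value_at(1.0), s_k):.3f}"
      " cGy h^-1 U^-1")
print(b.radial_dose_function(profile).round(3).to_string(index=False))
```

prints (one minute on one core):

```
dose-rate constant: 1.110 cGy h^-1 U^-1
 r_cm     g  rel_err
  1.0 1.000    0.000
  2.0 0.993    0.007
  5.0 0.989    0.007
 10.0 0.878    0.007
 15.0 0.617    0.008
```

The dose-rate constant matches the consensus Monte Carlo value for this
source in a 30 cm water sphere (1.115 ± 0.5%) within the run's statistics.
g(r) stays near 1 out to ~5 cm because scatter build-up almost exactly
compensates attenuation at ¹⁹²Ir energies, then falls as the phantom
boundary (15 cm) approaches and backscatter runs out. In bone the fall-off
is much steeper (g(15) ≈ 0.33) and in lung much flatter (g(15) ≈ 0.90) —
the heterogeneity effect that water-based planning ignores.

A CLI wraps the canned experiments and the comparison against the bundled
published reference tables:

```bash
brachymc run --experiment table1 --n 5e6 --seed 42 --out out/
brachymc compare --computed out/table1_radial_dose_function.csv \
    --reference radial_dose_function_30cm
```

`--full` switches any experiment to 10⁸-history statistics.

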