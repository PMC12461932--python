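# interphase

Quantitative analysis of enzyme–nanoparticle layers at the liquid–liquid
interfaces of biocatalytic Pickering emulsions.

Pickering emulsions — droplets stabilised by adsorbed solid nanoparticles
instead of surfactants — are a promising platform for interfacial
biocatalysis: a lipase and the stabilising particles both adsorb at the
oil/water interface, and how they share that interface controls activity
and emulsion mechanics. `interphase` implements the three quantitative
pipelines used to characterise such interfaces, plus a synthetic-data
generator with known ground truth for validating every stage:

* **Tensiometry** (`interphase.tensiometry`) — pendant-drop interfacial
  tension (IFT) traces. Surface pressure Π = IFT<sub>o/w</sub> − IFT;
  steady state declared when the least-squares slope of the final 3 min
  is below 0.005 mN·m⁻¹·min⁻¹; adsorption cooperativity

  α = (Π_sim − Π_particle) / Π_enzyme

  (α = 1: enzyme and particles adsorb independently; α < 1: particles
  partially block the interface); and the spherical-particle detachment
  energy E = πr²·IFT<sub>o/w</sub>·(1 ± cos θ)².

* **Interfacial shear rheology** (`interphase.rheology`) — oscillatory
  strain γ(t) = γ_A sin(ωt) and stress τ(t) = τ_A sin(ωt + δ) traces.
  Harmonic least-squares extraction of γ_A, τ_A and the phase angle δ;
  interfacial storage and loss moduli G′ᵢ = (τ_A/γ_A)cos δ and
  G″ᵢ = (τ_A/γ_A)sin δ in Pa·m; layer build-up (time-test) curves; and
  amplitude-sweep analysis — LVE plateau, yield point γ_y (onset of
  structural weakening) and flow point γ_f (G′ = G″ crossover by
  log-log linear interpolation).

* **Confocal droplet imaging** (`interphase.imaging`) — a diameter line
  profile is rotated in 1° increments through 360° around the droplet
  center, averaged into a representative profile, calibrated to enzyme
  concentration (g/L) by a linear standards fit, and reduced to droplet
  diameter, interfacial peak concentration, layer thickness (width of
  the peak at the fixed 0.5 g/L level — the initial enzyme
  concentration), and bulk concentration (10 pixels around the center).

The analysis steps that are fit-shaped are sklearn-style estimators
(`HarmonicFit`, `AmplitudeSweepAnalyzer`, `SteadyStateDetector`,
`IntensityCalibration`, `DropletAnalyzer`) with fitted `_`-suffixed
attributes and `get_params`/`set_params`; thin module-level functions
wrap them.

## Worked example

Generate a synthetic droplet image at the positively-charged-particle
condition (`NP+`: 5.17 µm droplet, 1.56 g/L peak, 0.75 µm layer,
0.098 g/L bulk; Poisson photon noise) and analyse it:

```
$ interphase simulate-droplet --preset NP+ --seed 7 --out demo
$ interphase analyze-droplet demo/droplet_NPpos_seed7.tiff
bulk_conc_g_per_L: 0.09806307742072931
diameter_um: 5.2
flags: []
interface_conc_g_per_L: 1.5432079968544192
interface_thickness_um: 0.7619154328271165
peak_position_left_um: -2.6
peak_position_right_um: 2.6
thickness_left_um: 0.7619154328271165
thickness_right_um: 0.7619154328271165
```

The recovered diameter (5.2 µm), peak concentration (1.54 g/L), layer
thickness (0.76 µm) and bulk level (0.098 g/L) match the generating
parameters to within one 0.1 µm pixel and a few percent — the residual
comes from pixelation and photon noise.

The same from the library, for tensiometry:

```python
from interphase import synthetic, tensiometry

trace, _ = synthetic.gen_ift_trace(ift0=8.1, ift_inf=5.0, seed=1)
res = tensiometry.steady_state(trace)
# res.plateau_reached      -> True
# res.plateau_ift_mN_per_m -> 5.012   (mN/m, mean of the last 3 min)
# res.pi_mN_per_m          -> 3.088   (Pi = 8.1 - 5.012)

tensiometry.cooperativity(pi_sim=5.0, pi_particle=2.0, pi_enzyme=4.0).alpha
# -> 0.75  (partial blocking: the joint pressure gains only 75 % of the
#           enzyme-only pressure on top of the particle-only pressure)
```

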