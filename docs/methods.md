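# Methods

This note documents the models and procedures implemented in
`interphase`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer.

## Tensiometry

**Surface pressure.** Π = IFT_o/w − IFT in mN/m, where IFT_o/w is the
clean oil/water reference tension. The default reference is 8.1 mN/m,
the midpoint of the 8–8.2 mN/m calibration range of the clean
1-octanol/water interface. Negative Π is reported as-is with a warning
flag rather than clipped: an interface where nothing adsorbs genuinely
fluctuates around zero.

**Steady state.** A trace is at steady state when the least-squares
slope of IFT over the trailing window (default 180 s) is below
0.005 mN·m⁻¹·min⁻¹ in absolute value. A regression slope is used rather
than an endpoint difference because it is robust to single-sample noise.
The comparison is strict (`<`); a slope within 10⁻⁹ (relative) of the
threshold counts as *not* reached, so the boundary case is deterministic
under floating-point jitter in the fit. The plateau IFT is the window
mean.

**Cooperativity.** α = (Π_sim − Π_particle)/Π_enzyme compares the
surface pressure of simultaneous enzyme+particle adsorption with the
sum of the single-component pressures: α = 1 means independent
(additive) adsorption, α = 0 a fully blocked interface. α is undefined
(an error, not NaN) when Π_enzyme ≤ 0. `cooperativity` accepts an array
for Π_sim, which gives the time-resolved α(t) as a convenience; plateau
values are the intended inputs.

**Detachment energy.** E = πr²·IFT_o/w·(1 − sign·cos θ)² in joules.
The widely used spherical-particle detachment energy carries a cos θ
in the squared factor; the `sign` argument (default +1) selects which
phase the particle detaches into, since both conventions occur in the
literature and the two are related by θ → 180° − θ. For a 15 nm-radius,
partially hydrophobic particle (θ ≈ 107.5°) at 8.1 mN/m the energy is
~9.7×10⁻¹⁸ J ≈ 2.3×10³ kT — adsorption is effectively irreversible,
which is why particle-stabilised droplets survive dilution and washing.

## Interfacial shear rheology

**Harmonic extraction.** Strain and stress are each projected by linear
least squares onto {sin ωt, cos ωt, 1} at the known drive frequency —
the instrument sets ω, so no spectral search or windowing is needed.
Amplitudes come from the quadrature components, the phase angle is the
stress-minus-strain phase wrapped to [0°, 180°); values in [0°, 90°]
are flagged physical. Phase differences within 10⁻⁶ degree of the wrap
point are snapped to 0° so that a −ε rounding error cannot masquerade
as a 180° phase. Traces must span ≥ 2 periods; a stress whose power at
the drive frequency is < 50 % of its total variance is flagged as not
harmonic. The fit is invariant to constant stress offsets by
construction (the basis includes a constant).

**Moduli.** G′ᵢ = (τ_A/γ_A)cos δ, G″ᵢ = (τ_A/γ_A)sin δ with γ_A as a
dimensionless fraction; user-facing strain is percent everywhere, and
the conversion happens in exactly one place (`moduli`). Moduli are
reported in Pa·m (interfacial, not bulk, units).

**Time tests.** One moduli point per oscillation block, ordered by
block timestamp; blocks must share ω and strain amplitude (5 % relative
tolerance, offenders listed in the error). A saturation detector applies
the same trailing-window slope pattern as the tensiometry plateau.

**Amplitude sweeps.** The LVE plateau is the mean G′ over the maximal
leading run of points within 5 % (relative) of the first point. The
yield point γ_y is where G′ first drops 5 % below the plateau — the
common rheometry convention, since "onset of structural weakening" has
no universal numeric definition — refined by linear interpolation of
log G′ vs log γ between the bracketing grid points. The flow point γ_f
is the G′ = G″ crossover, interpolated linearly in log-log coordinates
(matching how log-spaced sweeps are presented); with several crossings,
the first one with G′ decreasing is used. Both thresholds are
constructor parameters.

## Droplet imaging

**Center.** Centroid of the pixels above a global Otsu threshold. For a
droplet ring this is exact by symmetry; a ring touching the image border
triggers a warning (biased centroid), a uniform image an error. No
angular-variance refinement is applied: on ring images the centroid is
already subpixel-accurate (≤ 0.5 px in the tests).

**Profiles.** A full diameter profile is sampled at 1-pixel steps for
each of 360 angles in 1° increments (the 2× redundancy of diameters
versus radii is accepted; for symmetric droplets 180 and 360 angles
agree, and the tests check this). Sampling uses cubic-spline
interpolation (`interp_order=3`): bilinear resampling flattens a peak
whose decay length is ~1.6 px (the sharp outer flank of the NP+ ring)
by ~2.7 % when a ray crosses it diagonally, while cubic sampling keeps
the bias below 1 %. Out-of-frame samples are NaN and tracked by
per-position counts.

**Calibration.** Ordinary least squares intensity = gain·conc + offset
on the standards; the offset is fitted (not forced through the origin)
because detector background is real; a non-positive gain is an unusable
curve and an error. Concentrations are (I − offset)/gain clipped at 0,
with the clipped fraction recorded.

**Metrics.** On the averaged, calibrated profile: per side of the
center, the interfacial peak is the global maximum of that half
profile. Droplet diameter is the peak-to-peak distance — the only
landmark an interfacial-ring profile makes unambiguous (an edge-based
definition would need an arbitrary level). Interface concentration is
the mean of the two peak values. Interface thickness is the width of
each peak region at the fixed 0.5 g/L level — an absolute level (the
initial enzyme concentration of the aqueous phase), *not* a relative
half-max width — measured between the outermost crossings bracketing
each peak (scanning inward from the profile ends), so noise wiggles
inside the peak region cannot shrink it; the reported thickness is the
two-side mean. Bulk concentration is the mean of the 10 samples nearest
the center. A peak below 0.5 g/L leaves that side's thickness undefined
(NaN + flag); a peak that fails to rise above the bulk level is "no
resolvable interface" (error). Emulsion summaries report per-metric mean
and sample SD (ddof = 1; a single droplet reports SD 0 with an n = 1
flag), excluding flagged droplets and logging the exclusions.

## Synthetic data

The generators produce instrument-like inputs with known ground truth;
they are phenomenological, not physical simulations.

* **IFT traces**: bi-exponential decay
  IFT(t) = IFT_∞ + (IFT₀ − IFT_∞)[w·e^(−t/τ_fast) + (1−w)e^(−t/τ_slow)]
  + Gaussian noise. Adsorption kinetics show an initial rapid drop and
  a slower decline; the bi-exponential reproduces that shape without
  asserting an adsorption theory. Defaults: IFT₀ = 8.1, IFT_∞ = 5 mN/m,
  τ = 60/1500 s, 7000 s at 1 Hz (pendant-drop instruments log about one
  point per second), noise SD 0.02 mN/m.
* **Oscillation blocks**: γ_A sin(ωt) and τ_A sin(ωt+δ) with
  τ_A = |G*|·γ_A/100; defaults γ_A = 0.1 %, ω = 1 rad/s (the time-test
  protocol). Gaussian stress noise as a fraction of τ_A. Rejects fewer
  than 4 samples per period.
* **Amplitude sweeps**: G′(γ) = G′_LVE/(1+(γ/γ_s)²) with γ_s set so the
  5 % drop falls exactly at γ_y; G″ = G′·tan δ(γ) where the loss tangent
  rises monotonically from its LVE value through exactly 1 at γ_f. This
  parameterisation guarantees a single G′ = G″ crossing at the
  prescribed flow point for any gel-like layer — two independently
  decaying sigmoids cannot (for the NP− landmark values no crossing
  exists in that form). Defaults: G′_LVE = 2 mPa·m, G″_LVE = 0.5 mPa·m,
  γ_y = 1.65 %, γ_f = 13.9 %, grid 0.01–100 % at 10 points/decade.
* **Droplet images**: radially symmetric concentration field —
  background outside, interior plateau at the bulk level, and a
  two-sided Gaussian ring at radius d/2 with distinct inner/outer decay
  lengths (inner:outer = 2 by default, reproducing the sharper decay on
  the oil-facing side). The decay lengths are solved in closed form so
  the width of the peak at the 0.5 g/L level equals the requested ring
  width exactly. Intensity = gain·concentration (default 200 counts per
  g/L, keeping a 1.56 g/L peak at ~312 counts — Poisson-noise-limited
  like a real photon-counting confocal) with Poisson, Gaussian or no
  noise. Pixel size defaults to 0.1 µm. Presets `NP+`, `NP-` and
  `no-particles` carry the per-condition means and SDs (the
  `no-particles` condition is a sessile lipase drop, so its droplet
  diameter — 6 µm — and bulk level are package choices, not measured
  statistics).
* **Calibration standards**: intensity = gain·conc + offset + noise.
  No numeric calibration data are published for this system; the linear
  form with a free offset is the package's assumption.

What the generators do **not** emulate: optical sectioning and the
confocal PSF (rings are ideal fields sampled at pixel centers),
autofluorescence of the particles, multiple droplets per field, drift,
shear history in rheology, or any adsorption thermodynamics. Passing
the recovery tests therefore demonstrates the correctness of the
analysis chain on data with known truth — not robustness to every
artifact of real micrographs.

## Problem sizes

The recovery studies use 50 droplets per condition preset with Poisson
noise (150 images of roughly 90×90 px), amplitude sweeps on 41-point
grids, and oscillation blocks of 10 periods at 16–100 samples per
period; these sizes put the statistical errors well inside the
tolerances being checked while keeping the full suite around ten
seconds.

## Known limitations

* The flow-point interpolation assumes the sweep brackets the crossover;
  a sweep ending inside the transition reports "no flow point" rather
  than extrapolating.
* The diameter is peak-to-peak; for very thick layers relative to the
  droplet (ring width approaching the radius) the two definitions of
  "droplet size" (peak-based vs outer-edge-based) diverge, and the
  generator refuses diameter ≤ 2·ring width.
* Center detection assumes one droplet fully in frame; crowded fields
  need upstream segmentation.
* The detachment-energy printed form in the source literature is
  dimensionally ambiguous; this package implements the standard
  (1 ± cos θ)² expression and exposes the sign.
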