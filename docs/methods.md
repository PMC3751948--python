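# Methods

## The eye/source model

The radiometric chain treats the light source as a small emitter
(`S_source/u²` well below ~0.01 sr; a warning is raised otherwise) and
the eye as a single refracting element with coincident cornea, pupil
and nodal planes. Corneal irradiance follows the point-source
inverse-square law, pupil throughput multiplies by the pupil area
(circular disk, default 5 mm), and the retinal image area scales the
source area by `(u'/u)²` with `u' = 17 mm`. Composing the stages, the
source's size and distance cancel exactly:
`E_retina = L·τ·A_pupil/u'²`. This identity is enforced by a test at
1e-12 relative tolerance and is the module's main correctness anchor,
because every intermediate quantity also participates in unit
bookkeeping (radiance → irradiance → radiant power → irradiance).

**Solar input.** A tabulated solar spectral irradiance has no single
"source geometry", so two conversion rules are exposed:

* `direct-ratio` — the sun-gazing geometry: the tabulated irradiance is
  treated as corneal irradiance and imaged onto the solar-disk retinal
  image (`S_retina,sun = π(u'·tanθ)²`, angular radius θ = 0.266°). The
  geometric gain is `A_pupil/S_retina,sun ≈ 1.0e3`; this mode is the
  physically literal one, but it represents staring at the solar disk
  and produces retinal irradiances far beyond what an exposure device
  can (or should) reproduce.
* `transmittance-only` (default) — an orientation-averaged daylight
  exposure: the ocular-media filter `τ(λ)` shapes the spectrum and the
  absolute scale is fixed downstream by the exposure device itself: the
  brightest band's plate irradiance is driven at a configured peak
  (default 1.0 mW/cm², inside the device's 0–10 mW/cm² range) and all
  other bands scale with the filtered spectrum. The plate/retinal ratio
  stays exactly `f` in both modes.

**Ocular transmittance.** τ(λ) is shipped as an editable 18-anchor
table with the canonical shape (near-opaque below 390 nm, steep rise
through the violet, plateau 0.6–0.75 above 500 nm), interpolated with a
monotone PCHIP spline and clamped to [0, 1]. The anchors are a
synthetic stand-in — measured child-eye or standard-observer tables can
be dropped in via `tau_csv` — so no result here should be read as a
numeric reproduction of any measured retinal irradiance; tests that
need exactness use τ ≡ 1 or synthetic curves.

**Exposure scaling.** Plate irradiance = retinal band irradiance × f,
f = 66 by default, compressing a chronic exposure into the 18 h
protocol (6 h dark rest is carried as metadata). Radiant exposure
(dose) is plate irradiance × exposure seconds.

**Grid and resampling.** All spectra are linearly interpolated onto a
1 nm grid from 380 to 700 nm; outside a curve's support values are
either zero-filled (explicit opt-in) or an error is raised. Band
integrals are trapezoidal over [centre−5, centre+5] nm for rectangular
bands; the gaussian option integrates against a unit-area kernel with
FWHM equal to the band width (a sensitivity-analysis tool, not the
default).

## The A2E model

Absorbance is the sum of two gaussian peaks at 335 and 440 nm. Peak
positions are measured properties; the widths (30 and 45 nm FWHM) and
amplitudes (0.9 and 1.0 AU) are free shape parameters chosen to mimic
published curve shapes and are editable in the configuration. Emission
is a single gaussian at 640 nm (free A2E) or 620 nm (intracellular);
the blue shift is stored as an observation without mechanism.
Intracellular uptake is linear: `content = 0.032 + 0.25·c` ng per 1e5
cells for incubation at `c` µM. The endogenous intercept is a measured
value; the slope is a synthetic calibration constant (only the
*linearity* of uptake is an observed property), and ordinary least
squares on noiseless points recovers it to 1e-10.

## The synthetic assay generator

The generator emulates the measured structure of the screen so the
analysis stage can be tested end to end without laboratory data.

* **Design**: each experiment is one 96-well plate carrying five 10 nm
  bands plus a dark 16-well subdivision (fixed, by convention, at the
  lower-right block); each subdivision holds 4 A2E concentrations × 4
  contiguous wells. Bands are shuffled deterministically from the seed
  and chunked into plates, so 15 bands × 5 replicates = 15 plates.
  The dark control therefore accrues n = 15 experiment means while each
  band has n = 5.
* **Dark toxicity**: 4PL in A2E concentration with top 100%, bottom 0%,
  IC50 67.5 µM, Hill 4. The Hill slope is a free choice reproducing a
  visually steep sigmoid; only the IC50 anchors a measured value.
* **Photochemical hazard**: survival after exposure is
  `exp(−k·D·[Q(λ)·A(λ)·content(a2e) + φ·B(λ)])` with D the radiant
  exposure (J/m²), A the A2E absorbance at the band centre, content the
  intracellular A2E mass, B a gaussian violet kernel (centre 425 nm,
  FWHM 35 nm) carrying A2E-independent damage, and
  `Q(λ) = (440/λ)^12` a short-wavelength photochemical efficiency
  factor. Q is the package's own design: the absorbance kernel alone is
  symmetric about 440 nm while the sunlight-normalized dose profile
  rises toward the red, and without a steep efficiency term no
  parameter choice confines the statistically detectable damage to the
  420–450 nm bands — the asymmetry between 420 and 460 nm must come
  from the photochemistry, which is also the physically expected
  direction (higher photon energy, higher quantum yield of damage).
  The exponential-survival form keeps fractions in (0, 1] at any dose.
* **Channels**: viability = scale × dark sigmoid × survival × noise.
  Caspase = scale × (baseline × viable fraction + gain × A2E-mediated
  deficit) × noise, where the A2E-mediated deficit is
  `s_free − s_total` (survival under the violet kernel alone minus
  total survival); scaling the baseline by the viable fraction means
  cell loss without caspase induction does not inflate the per-viable-
  cell apoptosis ratio, so apoptosis is A2E-dependent by construction.
  Necrosis = scale × level × (1 + 0.025·a2e) × noise — light-
  independent, rising ~2× by 40 µM, hence null against the dark control
  at the same concentration.
* **Noise**: per-well multiplicative log-normal noise with CV 0.10
  (mean-1 parameterisation) on every channel, and a per-experiment
  log-normal scale factor (SD 0.15) standing in for varying cell
  densities — the feature that motivates normalizing each experiment to
  its own dark untreated wells.
* **Calibration**: k = 3.4e-6 per (J·m⁻²·AU·ng/1e5 cells) and
  φ = 0.30 were calibrated, on seeds disjoint from any used in the
  tests, so that at the default plate irradiances the apoptosis channel
  is significant exactly at 420–450 nm at 20 µM while A2E-free
  viability losses stay modest (~20–25%) and restricted to the violet
  bands. These are synthetic constants, not measurements. At the
  calibrated dose the viability collapse at the peak bands is extreme
  (survival ≪ 1% at 430–440 nm, 20 µM), which exaggerates the assay's
  dynamic range; the significance *pattern*, not the effect magnitude,
  is the calibrated quantity. A known artefact of the linear-scale,
  pooled-variance inference is that at 40 µM the detectable set can
  shrink toward the centre bands (the enormous variance of the peak
  groups raises the pooled threshold).

## Analysis stage

* **Normalization**: viability and necrosis are divided by the mean of
  the same experiment's dark 0 µM wells (×100); apoptosis is the
  per-well caspase/viability ratio normalized the same way. The
  experiment scale factor cancels exactly when noise is off, and
  normalizing already-normalized data is the identity. Missing dark
  untreated wells fail loudly; zero-viability wells are excluded from
  the ratio with a warning.
* **Unit of replication**: wells are averaged within an experiment
  first; all inference runs on experiment means (n = 4–6 in the
  emulated design), never on wells.
* **Inference**: at each A2E level, one-way ANOVA across all groups
  (bands + dark control) gates Dunnett many-to-one comparisons against
  the dark control at the same level (two-sided). The gate follows the
  assay's published procedure even though it is conservative. Dunnett
  p-values come from the exact multivariate-t distribution
  (scipy), with a fixed internal integration stream so reported
  p-values are reproducible to ~1e-3. Bands observed in fewer than two
  experiments are excluded with a warning. Unadjusted two-sample
  t-tests are exposed separately for planned pairwise contrasts
  (uncorrected by default, matching the assay's usage).
* **Dose-response**: 4PL least squares with multi-start over Hill ∈
  {0.5, 1, 2, 4, 8}, IC50 constrained positive; flat data and
  non-convergence are flagged rather than raised; a fit whose IC50
  exceeds the tested dose range is flagged as extrapolated. On the
  default campaign (doses ≤ 40 µM, deliberately below dark-toxic
  levels) the within-campaign dark fit is under-determined and
  indicative only; IC50 recovery is validated on the extended dose set
  {0, 12.5, 20, 40, 60, 80, 100} µM, where the noise-free fit recovers
  the generating parameters to 1e-6 relative and 200 noisy replicates
  recover the IC50 with <10% median error.
* **Toxic range**: the longest run of significant bands spaced 10 nm
  apart inside the blue-green block, reported with the ±5 nm band
  half-width (e.g. bands 420–450 → interval 415–455 nm); shorter runs
  and the 630 nm control are listed as secondary.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline's algebra, statistics and
plumbing are correct under the generator's assumptions: multiplicative
noise, exchangeable experiments, exponential survival, gaussian
kernels. They do not validate the biological magnitudes (hazard
coefficient, apoptosis gain, uptake slope are synthetic), nor the real
shape of τ(λ), nor plate-position or edge effects, pipetting drift,
photobleaching kinetics, or any time-course behaviour — none of which
are modelled. Real data in the same long CSV schema can be analyzed
unchanged; the generator's defaults only define the simulated study
conditions.

## Determinism and problem sizes

Every stochastic step flows from one integer seed (band shuffling,
experiment scales, well noise); rerunning any command with the same
seed and configuration is byte-identical, and output headers carry the
seed and a configuration digest. Default problem sizes — 15 plates ×
96 wells per run, 2000 simulated four-plate experiment sets for the
null-calibration check, 200 replicates for IC50 recovery, 20 seeds for
the action-spectrum check — were chosen to keep Monte-Carlo error well
below the tested tolerances while the full suite stays inexpensive on a
single CPU.
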