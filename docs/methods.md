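# Methods

This note documents the models behind `nanokymo`, the defaults they use,
and what the synthetic-data generator does and does not emulate.

## The experimental system being modeled

λ-DNA (48.5 kbp) labeled with the bis-intercalator YOYO-1 is confined in
rectangular nanochannels (100 × 150 nm cross-section), where it stretches
to a fraction of its contour length and is imaged by fluorescence
microscopy as a short movie. Three families of observables are analyzed:

1. **Geometry** — per-molecule extension along the channel, the standard
   deviation of that extension over frames (thermal fluctuation), and the
   background-adjusted emission intensity (proportional to bound dye).
2. **Photokinetics** — per-dye photobleaching (exponential intensity
   decay) and dye-mediated photonicking; two single-strand nicks on
   opposite strands within a few basepairs produce a double-strand break
   and the molecule fragments.
3. **Binding** — bulk fluorescence titrations of YOYO-1 against DNA,
   fitted with a simplified McGhee–von Hippel isotherm to extract the
   apparent binding constant K_a and the binding-site size n (bp per
   bound dye). Mg²⁺ and ATP modulate K_a; free YOYO-1 is essentially
   non-fluorescent, so signal ∝ bound dye.

## Synthetic image stacks (`synthdata`)

Each molecule is rendered as a 1-D boxcar of its per-frame extension on
its nanochannel line, convolved with a Gaussian PSF, scaled by the number
of surviving dyes, and read out with Poisson shot noise, Gaussian read
noise, gain, and offset.

- **Extension fluctuations** are a discrete Ornstein–Uhlenbeck process:
  stationary mean `extension_mean`, stationary SD `extension_sd`,
  correlation time `ou_relaxation`. This is a surrogate chosen for its
  tunable, stationary Gaussian statistics — it is not a polymer-dynamics
  simulation. Defaults: mean 5.0 µm, SD 0.3 µm, τ = 0.5 s, matching the
  order of magnitude of nanoconfined λ-DNA at ~100 mM ionic strength.
- **Optics/camera**: pixel 110 nm (100× objective with an ~11 µm camera
  pixel), PSF σ 100 nm, gain 1, read noise 2 counts, offset 100 counts,
  5 photons per dye per frame. The illumination and camera parameters are
  testability placeholders; no instrument was characterized for them.
- **Imaging conditions**: the default `SimConfig` mirrors the
  extension/intensity condition (15 frames × 100 ms, 1:10 dye:bp);
  `SimConfig.photodamage()` mirrors continuous-illumination movies
  (80 frames × 50 ms, per-dye bleach rate 0.5 s⁻¹, nick rate
  5×10⁻³ s⁻¹ per bound dye). The nick rate was set once so that a
  realistic minority (~20 %) of molecules fragment within a movie; much
  lower rates would never complete an opposite-strand nick pair within
  the 10 bp DSB window on a 48.5 kbp genome.
- **Bleaching** is per-dye binomial survival with probability
  `exp(-bleach_rate·Δt)` per frame, so the expected intensity decays as a
  single exponential.
- **Double-strand breaks**: nicks arrive as a Poisson process with rate
  `nick_rate × (bound dyes)`, uniform in position, random strand. A DSB
  forms when a new nick lands within `dsb_window_bp` (default 10 bp) of
  an opposite-strand nick; the molecule then splits at the break and the
  two fragments separate at `drift_speed` (default 1 px/frame — arbitrary;
  it only needs to make splits visible). An exhaustive all-pairs scan
  (`first_dsb_time`) is kept as an independent oracle for tests.
- **Conformations**: circles render at 0.58× the monomer extension with
  reduced SD (self-hybridized overhangs roughly halve the apparent
  contour), fragments at a uniform 0.20–0.45× with SD scaled as √factor,
  concatemers at 2× (dimers). These factors are generator conventions,
  chosen to be cleanly separated in the (extension, SD) plane.
- **Saturation**: dye loading is capped at 1 dye per 4 bp.

What the generator does **not** emulate: hydrodynamic loading, focus
drift, channel-to-channel variation, non-uniform illumination, dye
redistribution/self-quenching, external (non-intercalative) binding at
high dye load, and real polymer dynamics beyond the OU surrogate. Passing
tests therefore demonstrate the *analysis chain* is correct under the
stated statistical assumptions, not that it is robust to every real
microscope artifact.

## Kymograph analysis (`kymo`)

Channel lines are local maxima of the transverse profile of the
time-averaged image; per line, contiguous runs above background +
`snr_threshold`·σ (background and σ estimated from the lowest quartile of
the profile, since a molecule can span half the field of view) become
molecule boxes. Kymographs sum ±1 row around the line.

**Edges** are located per column at 0.5× the intensity plateau after
subtracting the median of the flanking pixels, with linear subpixel
interpolation; the plateau is the median of background-subtracted values
at or above half the maximum. The half-plateau criterion is standard for
PSF-blurred boxcar profiles: for a symmetric PSF the half-maximum
crossing sits at the true step position, making the measured width
first-order insensitive to blur. Frames with ≥ 2 segments separated by
≥ 2 px are flagged as split and excluded from geometry summaries (they
are the input to fragmentation detection instead); molecules with < 3
usable frames are dropped with a logged reason.

**Summaries**: extension = mean over frames of (right − left); extension
SD = *population* SD over frames (documented because SDs are compared
across molecules); mean intensity = background-subtracted signal averaged
over time and position between the edges. Intensities are comparable only
within one acquisition setting.

## Classification (`classify`)

Default method is deterministic mode + robust-MAD gating: the monomer
cluster is the 2-D KDE mode of (extension, SD); points within 3 robust
MADs on both axes are linear monomers; higher extension → concatemer;
lower extension → circle if within 0.5–0.7× the monomer mode with
below-median SD, else fragment. MADs are estimated from the cluster core
(±15 % of the mode) so that other populations do not inflate them. All
gates derive from the data, making labels invariant to a common rescale
of the extensions. A Gaussian-mixture alternative (`method="gmm"`,
components chosen by BIC) is available; the deterministic default was
preferred because it cannot fail to converge and is reproducible without
a random state. Only molecules classified as full-length linear monomers
enter downstream extension/intensity statistics.

## Photokinetics (`photokinetics`)

- **Bleach decay**: nonlinear least squares of `A·exp(-α·τ) + B`, by
  default on the mean trace of the batch; initials A = first − last,
  B = last, α from a log-linear regression. A flat trace returns α = 0
  with A folded into B and a degeneracy flag.
- **Fragmentation events**: a kymograph column is "split" when it has
  ≥ 2 above-threshold segments separated by ≥ 2 px; the event time is the
  start of the first run of ≥ 3 consecutive split columns. The
  persistence filter rejects single-frame flickers; it also means
  detection lags the true break by ~2 frames (the gap must open past the
  PSF before it is visible).
- **Fragmentation kinetics**: fragment fraction y(t) is fitted with
  y = r·tⁿ (log–log OLS initializer, then nonlinear least squares) and
  extrapolated to t50 = (0.5/r)^(1/n), the exposure at which half the DNA
  is fragmented. Intact-fraction series are isotonically regularized
  (monotone non-increasing) before fitting by default. The kinetic
  exponent is named `n_exp` throughout to avoid collision with the
  binding-site size `n_site`.
- **Densitometry**: lanes are baseline-subtracted with a rolling minimum
  (defaulting to a whole-lane window, i.e. a constant offset — narrower
  windows would eat the broad fragment smear); intact = integral over the
  band window, fragment = integral over all higher-mobility positions
  ("below" the band, i.e. larger migration distance); fractions are
  normalized to their sum and are therefore invariant to exposure scale
  and baseline offset.

## Binding (`binding`)

The isotherm `L_T = L_f + K_a·L_f/(1 + K_a·L_f)·(S_T/n)` is solved for
free ligand in closed form: clearing the denominator gives
`K_a·L_f² + (1 + K_a·S_T/n − K_a·L_T)·L_f − L_T = 0`, whose unique
non-negative root is evaluated with the cancellation-safe q-formulation.
The solver is exercised against a bracketing-bisection oracle at 1e-12
relative tolerance.

`fit_mvh` runs weighted nonlinear least squares over
(log₁₀K_a, n_site, scale[, offset]) from a 3×3 grid of starts. Weights
default to 1/signal (floored at 5 % of the maximum), matching the
multiplicative noise of fluorescence plate readers. The fit warns when
the data do not reach 80 % of the fitted plateau (K_a weakly identified).

**Identifiability limit**: with S_T = 1 µM bp and a 1:20→1:1 design, the
titration carries good affinity information for K_a·S_T/n up to ~100. For
K_a ≳ 10⁹ M⁻¹ the curve degenerates to a stoichiometric break; fitted
K_a is then unbiased in the log but scattered over roughly half a decade
at 2 % noise, while n_site (set by the plateau and initial slope) remains
well determined. The recovery tests assert the tight tolerance only in
the identifiable regime and log-unbiasedness beyond it.

Hill (`log(θ/(1−θ))` vs `log L_f`, slope 1 for this non-cooperative form)
and Scatchard (`r/L_f` vs `r`, slope −K_a, x-intercept 1/n) companions
use L_f recomputed from the fitted parameters and exclude occupancies
outside (0.05, 0.95).

Fluorescence is assumed strictly proportional to bound dye (no free-dye
background term by default; an offset is available behind a flag), and
each (Mg²⁺, ATP) condition is fitted independently.

## Confinement theory (`polymertheory`)

- **Ionic strength**: I = ½Σcᵢzᵢ², with Tris speciated by
  Henderson–Hasselbalch (pKa 8.1 at 25 °C; the protonated fraction
  carries matching Cl⁻). The background buffer (10 mM Tris-HCl pH 7.5 +
  100 mM NaCl) evaluates to 108 mM. ATP defaults to the `mgatp_pairing`
  convention: ATP⁴⁻ with monovalent counterions, paired 1:1 with
  available Mg²⁺ into [MgATP]²⁻ up to the limiting reagent (the complex
  dominates at mM Mg/ATP); a `free_ions` convention is selectable, and
  the convention matters to the computed upper end of the experimental
  range, so it is part of the reported output.
- **Contour length**: 0.34 nm/bp, growing linearly with dye load to +38 %
  at saturation (1 dye / 4 bp).
- **Persistence length**: 50 nm bare plus an OSF-type electrostatic term
  0.0324 nm·M / I.
- **Effective width**: a Stigter-type effective diameter, log-log
  interpolated from a monotone table (31.6 nm at 5 mM down to 2.8 nm at
  1 M). The table constants are documented stand-ins following the
  standard screening trend; they are exercised by a dual-implementation
  interpolation test, not against published tabulations.
- **Extension**: extended-de-Gennes scaling
  `ext = prefactor · L_c · (p·w/D²)^(1/3)` with D the geometric mean of
  (width − w, height − w) (arithmetic mean behind a flag); when
  D < 2p the Odijk deflection formula
  `L_c·(1 − 0.09137·Σ(Dᵢ/p)^(2/3))` is used and labeled. The prefactor is
  a calibration constant (default 1.0, or set once from a control
  observation via `calibrate_prefactor`, which makes Ext_O/Ext_T = 1 at
  the calibration condition by construction). Ratios below 1 at other
  conditions then indicate effects beyond ionic-strength scaling.

## Pipeline (`pipeline`)

`run_condition_grid` wires the modules over a (Mg²⁺, ATP, dye:bp) grid.
Conditions act only through generator parameters: free Mg²⁺ (after 1:1
MgATP pairing) interpolates the apparent K_a log-linearly between the
control (2.8×10⁸ M⁻¹) and 5 mM (1.9×10⁷ M⁻¹) endpoints; the bound-dye
fraction then follows from the isotherm at the staining condition
(2 µM bp), and it drives the rendered intensity and nicking load, while
the bleach rate rises linearly with free Mg²⁺. This wiring is a scenario
for exercising the pipeline, not a mechanistic model. Every cell derives
its seed deterministically from the run seed; cell failures are logged
with the cell identity and the grid continues with a flagged partial
report. Outputs (molecules.csv, classes.csv, kinetics.json, binding.json,
report.md) are byte-reproducible for a fixed config and seed.

## Problem sizes and numerical choices

Test simulations use 25–320 molecules per stack, 15-frame imaging movies,
80-frame photodamage movies, and 100-replicate titration ensembles —
sizes chosen so each statistic (means, medians, rates) is estimated well
inside its asserted tolerance. Ties and degenerate inputs: an all-flat
bleach trace returns α = 0 with a flag rather than failing; a kymograph
with no usable frame raises naming the molecule; classification refuses
fewer than 20 molecules instead of returning unstable gates; the
free-ligand solver clips its root to [0, L_T] to absorb last-ulp
round-off.

## Known limitations

- The extension model's prefactor and the effective-width table are
  calibration-grade stand-ins; absolute Ext_T values should not be
  compared against literature without recalibration.
- The classifier's circle gate is a heuristic band (0.5–0.7× monomer
  extension, low SD) and is not exercised against rendered circles in
  the default mixtures.
- Gel simulation places the whole fragment smear strictly below the
  band; real smears can overlap the band foot, which would bias
  densitometry in a way the round-trip tests do not probe.
- The isotherm is the simplified single-site form; neighbor-exclusion
  (full McGhee–von Hippel) and any Mg·ATP speciation equilibrium beyond
  1:1 pairing are out of scope.
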