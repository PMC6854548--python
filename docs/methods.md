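# Methods

`oscbeam` implements a source-space oscillatory analysis of epoched MEG
data of the kind used to dissociate anterior- and posterior-temporal
responses in semantic-priming paradigms: a coarse whole-brain
localisation phase followed by fine time-frequency condition contrasts
at points of interest (POIs). Because raw recordings of this kind are
rarely shareable, the package ships a synthetic-data generator with
known ground truth, and every statistical guarantee is validated
against that ground truth.

## Forward model

The head is a homogeneous conducting sphere (default radius 9 cm,
origin at the sphere centre, z towards the vertex). The external
magnetic field of a current dipole follows the classical closed-form
spherical solution; sensors are ideal point magnetometers that read the
projection of **B** onto their orientation. Two consequences of the
spherical geometry anchor the tests:

* a dipole moment parallel to the radius produces no external field;
* the external field does not depend on the sphere radius while the
  source remains inside.

"Multiple spheres" fitting is exposed as optional per-channel (centre,
radius) overrides; with identical overrides the single-sphere solution
is reproduced exactly. Sources within 1 nm of a sphere centre are
rejected (the closed form degenerates there) rather than regularised.
Sensor arrays are Fibonacci spirals over a spherical cap (default 248
channels, 12 cm helmet radius, 125° coverage), a stand-in for a
whole-head magnetometer helmet. Source lattices are cubic grids
(default 5 mm) offset by half a spacing so no point falls on the
sphere centre, with a half-spacing margin to the surface.

## Synthetic data

The generator emulates a primed semantic-decision recording: 248
magnetometers at 678.17 Hz, 1500 ms epochs starting 800 ms before the
onset of the second word of a pair, with conditions `taxonomic`,
`thematic_strong`, `thematic_weak` and `unrelated` at 95 trials per
related condition (a `trial_scale` factor shrinks this for fast runs).
Each injected effect is a current dipole at a chosen location carrying
a cosine at a chosen frequency under a Hann envelope over a chosen
window, with per-condition amplitudes. The `phase_locked_fraction`
splits the amplitude into an evoked part (constant phase across trials)
and an induced part (fresh uniform phase per trial), which is exactly
the evoked/total distinction the analysis manipulates. Background
activity comes from 200 random interior dipoles with tangential
moments and 1/f-shaped unit-RMS time courses at 10 nA·m each — enough
spatially structured rank to make adaptive beamformers well-posed —
plus white sensor noise (2e-13 T per sample). No SNR is implied by the
emulated study itself; the defaults were chosen once so that effects in
the 10–100 nA·m range sit comfortably above the noise floor while
single-trial data remain visibly noisy. About 10% of trials are flagged
as catch trials and dropped from every MEG analysis. Artefact screening
is a simple peak-amplitude threshold per trial, a deliberate stand-in
for visual inspection.

What the generator does **not** emulate: realistic eye-blink or
muscle topographies, reference-channel noise, head movement,
inter-individual anatomy (all participants share the sensor geometry
and head sphere), or amplitude variability between participants beyond
what the noise induces. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under its own
assumptions, not robustness to real-world artefacts.

## Beamformer and NAI maps

The vectorised LCMV beamformer solves, per lattice point,
`W = (L' C⁻¹ L)⁺ L' C⁻¹` with `L` the channels × 3 lead field and `C`
the regularised data covariance. In a spherical conductor the radial
source direction is externally silent, so `L' C⁻¹ L` has rank 2 at
every point; the pseudo-inverse is a truncated eigen-inverse
(eigenvalues below 1e-10 of the maximum are dropped) that keeps the
detectable tangential subspace and gives exact unit gain for full-rank
lead fields. Points with effective rank < 2 are rejected.

Covariances are sample covariances pooled over trials after zero-phase
4th-order Butterworth band-pass filtering of the whole epoch, without
mean removal (the band-pass removes DC, and zero data must give a zero
matrix). Regularisation is diagonal loading, `C + λ·mean(diag(N))·I`,
with λ = 0.05 by default; the noise covariance `N` defaults to the
passive-window (−700..−500 ms) estimate, with an identity-scaled
alternative available. The loading level assumes covariances estimated
from at least roughly 40 trials; with far fewer samples the weights
overfit the sample covariance and λ should be raised.

Source power is `tr(W C W')` over the three orientations, and the
Neural Activity Index divides by the projected noise,
`NAI = tr(W C W') / tr(W N W')`, which removes the depth-dependent
noise amplification of raw beamformer power. When the data covariance
equals the noise covariance the NAI is exactly 1 everywhere.

For the whole-brain active-vs-passive contrast the two maps of a
contrast share weights computed from the covariance pooled over both
windows. This is the package's default because it makes the two maps
exchangeable under the null: with per-window weights the passive map is
identically 1 (its numerator and denominator coincide) while
finite-sample overfitting biases the active map below 1, which breaks
the sign-flip permutation logic. Per-window weights remain available
for the NAI operation itself.

## Whole-brain inference

Per point, a paired t statistic across participants compares active
(0–200, 200–400, 400–600 ms) against passive (−700..−500 ms) NAI in
four bands (5–15, 15–25, 25–35, 35–50 Hz). Family-wise error is
controlled by the permutation maximum statistic: each of 10,000
permutations flips each participant's active/passive labels (whole map
by default, preserving spatial covariance; per-point flipping is an
explicit mode) and records max |t|; points at or above the top-5%
quantile of those maxima survive. Zero-variance points carry t = 0,
are flagged, and never survive. Two-sided |t| is the default; the
one-sided variant is a switch.

## POI time-frequency analysis

The virtual electrode at a POI applies condition-specific weights
(covariance over the full epoch, 5–50 Hz) to every trial. Evoked power
transforms the trial average; total power averages single-trial power;
both sum squared magnitudes over the three orientations. The discrete
S-transform is computed in its FFT formulation with the standard
frequency-domain Gaussian window `exp(−2π²m²/n²)` (σ_f = f in bin
units, i.e. a 1/f-wide time window); the DFT is normalised by 1/N so
that the time average of S(τ, f) equals the Fourier coefficient H(f)
exactly — the identity used to test it. A variable-window filter-bank
variant used by some older analysis suites is not reproduced; the
standard transform is well-defined and testable.

Power is converted to percent signal change per frequency bin against
the −700..−500 ms baseline, using one baseline pooled across the
conditions entering an analysis. The pooled baseline matters: with
per-condition baselines, the baseline estimation error of each
condition multiplies the (large) evoked power and manufactures smooth
spurious condition differences under the null. Maps are then averaged
into half-open 25 ms × 2 Hz tiles (60 × 23 under the defaults,
lower-edge labelled).

## Tile statistics

A tile enters the significance contours only if (a) the condition
difference reaches p < .05 and (b) at least one contributing condition
departs from baseline at p < .01 — both strict. The difference p-value
is, by default, a sign-flip maximum-statistic adjusted p (1000
permutations): the mixed-model machinery this per-tile test stands in
for carried its own experiment-wise multiplicity control, and on the
smooth S-transform field raw per-tile p's would let chance clusters
through at far above the nominal rate. Raw p's are available via
`adjust="none"`. Baseline tests are one-sample t's against 0% change.

Cluster-extent correction follows the random-fill recipe: given the
observed fill rate (share of tiles passing both criteria), significant
tiles are scattered uniformly over the grid (10,000 Monte-Carlo draws,
or exhaustive enumeration on small grids), the distribution of the
maximal contiguous cluster is recorded, and the smallest size k* with
tail probability below α/12 (α = .05 Bonferroni-split across 4 sites ×
3 contrasts) becomes the reporting threshold. Contiguity defaults to
edge adjacency (4-connectivity, the conservative reading of
"contiguous"); 8-connectivity is a switch and every report records the
choice. Sub-threshold clusters that met both tile criteria are kept
separately as "dashed" regions. The k* for a given fill rate is a
data-dependent quantity; the acceptance script reports the value
computed at the documented worst-case 7.5% fill on the 60 × 23 grid
for both adjacencies.

Behavioural catch-trial tables are tested with paired two-tailed t
tests (RT and accuracy; taxonomic vs strong, taxonomic vs weak, strong
vs weak) after removing participants whose overall catch accuracy is
below 75% (strict). With the generator's study-sized default — 20
participants, one performing near chance — 19 remain and every
contrast has 18 degrees of freedom.

## Validation studies and problem sizes

`oscbeam.studies` packages the recurring validation recipes; the test
suite and `scripts/acceptance.py` run them at these sizes:

* **Localisation**: 20 single-dipole scenes (64 channels, 40 trials,
  60 background dipoles, 200 nA·m source at 30 Hz — band-limited
  sensor-level SNR well above 10), full 5-mm lattice; success = NAI
  peak within one spacing.
* **FWER calibration**: 200 global-null cohorts × 500 permutations ×
  100 points × 12 participants; the cohort false-alarm fraction must
  sit inside the 99% binomial interval around 0.05.
* **POI recovery**: 20 cohorts of 19 participants (48 channels, 16
  trials/condition, 40 background dipoles). All conditions share a
  common 10 Hz evoked onset (50 nA·m, 0–300 ms); only
  `thematic_strong` adds a 20 Hz burst (80 nA·m, 150–500 ms) at the
  posterior-temporal POI. Ground-truth tiles are those where the
  injected burst's own noise-free tile power reaches 25% of its peak —
  defined from the injection, never from analysis output. Sensitivity
  is the share of truth tiles retained in the strong-vs-taxonomic
  contrast; specificity is the fraction of cohorts whose
  taxonomic-vs-weak (exact null) contrast retains any cluster.

## Numerical choices and degenerate inputs

Eigenvalue truncation at 1e-10 of the maximum for the beamformer Gram
matrix; covariance symmetrised after estimation; windows half-open
`[t0, t1)`; tile and baseline masks half-open; permutation thresholds
are empirical quantiles with survivors at "equal or higher"; p-value
ties at the thresholds are excluded (strict inequalities); zero-variance
tiles and points get t = 0, p = 1 and a flag. Monte-Carlo draws use
`numpy.random.default_rng` seeded explicitly everywhere; identical
configurations and seeds reproduce outputs bit-for-bit.

## Known limitations

* The spherical forward model cannot represent realistic head shapes;
  per-channel spheres are provided but no fitting procedure is.
* The NAI contrast shares weights across the two windows; condition
  contrasts with very different covariance structure may prefer the
  per-window mode, which is not calibrated under the null here.
* The random-fill cluster null ignores the spatial correlation of the
  tile field; the max-stat adjusted tile p's carry the experiment-wise
  control, and the cluster stage is a secondary filter, as in the
  procedure it reproduces.
* Behavioural and MEG simulations are independent; no brain-behaviour
  coupling is modelled.
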