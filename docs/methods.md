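# Methods

`urbansense` re-implements, on a fully synthetic monitoring campaign, an
analysis pipeline for estimating spatially and temporally resolved noise
and fine particulate matter (PM2.5) from street-level images in a West
African city. This note documents the generative model, the modelling and
evaluation procedures, the numerical choices, and what the synthetic
results do and do not show about real data.

## The synthetic campaign

The generator (`synthetic_city`) emulates a 15-month field campaign:
ten *fixed* sites instrumented April 2019 – June 2020 and 135 *rotating*
sites instrumented for one week each, spread over four land-use classes
(commercial/business/industrial, informal settlement, formal residential,
other). Each site carries one or two cameras taking a frame every 5
minutes and co-located monitors recording 1-minute averaged noise (dBA)
and PM2.5 (µg/m³). Pollution timestamps denote the end of each averaging
window; frames are stamped at the capture instant.

### Latent structure

* **Activity.** A nonnegative diurnal latent
  `a(t) = A_s · ½(1 − cos(2π(h−3)/24))` (peak 15:00, trough 03:00), with
  site amplitude `A_s` set by land use plus seeded jitter. Activity is
  the common driver of street objects and local emissions.
* **Noise.** `noise(t) = β_s + κ·a(t) + ε`, with site baseline `β_s`
  (dBA), `κ = 12` dBA per unit activity, and Gaussian error (SD 1.5 dBA).
* **PM2.5.** Log-normal:
  `log pm(t) = λ_s + r(day) + 1[Harmattan]·log m + γ·a(t) + AR1(t)`
  with site baseline `λ_s`, a day-level regional effect `r ~ N(0, 0.35)`
  shared by all sites (dust and non-local transport), a Harmattan
  multiplier `m = 2.5` inside the November 1 – February 28 window
  (boundaries inclusive), a local-traffic term `γ = 0.45` per unit
  activity, and AR(1) log-noise (φ = 0.9, SD 0.12).
* **Object counts.** Per category `o`,
  `count_o(t) ~ Poisson(exp(a_o + b_o·a(t)) · v(t))` over the 20-category
  street-object vocabulary (persons, cars, taxis, tro-tros, umbrellas,
  …). Night visibility `v = 0.4` reflects reduced detectability in the
  dark. Four categories (cookstove, loudspeaker, market vendor, bus) are
  configured near-absent, mirroring their sparsity in real detector
  output; the remaining 16 form the model feature vector.
* **Frames.** 64×64 RGB scenes: sky/ground gradient (dark with a few
  bright lamps at night), one coloured rectangle per counted object, and
  a visual PM2.5 encoding — an additive red tint with matched blue
  decrease proportional to `log(pm/10)`, plus Gaussian blur and contrast
  compression growing with `log pm` (the Harmattan haze signature).
  Rectangles are deliberately schematic: the image model needs learnable,
  countable visual tokens, not photorealism.
* **Pathologies.** Some cameras' clocks reset to the 2017-01-01 factory
  default at deployment (stamped times then run 0, 5, 10, … minutes from
  that epoch); 2% of pollution rows are dropped; 0.5% of frames and rows
  are written as unreadable bytes. A log-sheet retains every deployment's
  true start time.

### Scaling

Fixed-site deployments span the full 15 months but record on a subset of
*recording days* (7 by default, evenly spaced; clock-failed sites record
a contiguous block from deployment start because the repair procedure
reconstructs a contiguous 5-minute grid). Rotating sites record 1 of
their 7 deployment days. This keeps the default 145-site world at about
60,000 frames and 300,000 pollution rows — generable in minutes on one
CPU — while preserving the fixed sites' roughly seven-fold per-site data
volume. Day/night uses a fixed clock rule (06:00–18:00 = day), chosen
over solar geometry for determinism.

The marginal pollution distributions per land-use class are plausibility
choices (e.g. CBI baseline ≈ 52 dBA, 22 µg/m³), not calibrated to any
real city.

## Ingest and pairing

`ingest_pairing` reconstructs the analysis Record table from raw
artifacts:

1. **Timestamp repair.** A camera whose earliest stamp predates 2018 is
   treated as clock-failed; its k-th frame (sorted by stamp) is
   re-stamped `logsheet start + k·5 min`. A failed camera missing from
   the log-sheet is a hard error naming the camera.
2. **Exclusion window.** Records dated 2020-03-23 through 2020-05-11
   (closed interval — a conservative reading of "from … to …") are
   dropped, emulating the pandemic maintenance gap.
3. **Pairing.** Each frame takes the nearest-in-time pollution value
   within ±30 s, *independently* for noise and PM2.5 (their usable rows
   differ, and real campaigns report different match rates per
   pollutant). Equidistant candidates, including rows exactly at the
   tolerance, resolve to the earlier row — a deterministic tie rule
   verified against a brute-force oracle. Unmatched frames keep missing
   values; corrupted rows and undecodable frames are skipped with logged
   counts, never fatal. Co-located cameras receive identical values.

## Classes and splits

Noise is binned into 10 ordinal classes (≤39, 40–<45, …, 75–<80, ≥80
dBA) and PM2.5 into 11 (0–<5, …, 100–<150, ≥150 µg/m³). Interior bins
are right-open; a PM2.5 value exactly on a boundary joins the upper
class. The printed noise scheme leaves (39, 40) dBA formally unassigned;
values there are closed upward into the 40–<45 class.

Split plans (serialisable to JSON for exact replay):

* **1a** (same site, different times): a seeded uniform 10% of a fixed
  site's records is the test set; the remainder splits 75/25 into
  train/validation. The test draw is keyed to the *site* and seed so
  every design evaluating at that site shares the same test records.
* **1b** (cross-site): models trained at one fixed site are evaluated on
  another site's 1a test set, making same-site and cross-site numbers
  directly comparable.
* **2a**: train on nine fixed sites, test on all records of the tenth.
* **2b**: rotating *sites* are randomly partitioned into 10 folds (13–14
  sites per fold for 135); each fold's records are a test set and the
  remaining sites the training pool.
* **2c**: two arms on one shared test set (a 2b fold): the few-sites arm
  trains on the fixed sites' abundant records, the many-sites arm on the
  rotating training sites' sparser records.

## Models

Both families are ordinal classifiers over a class scheme and expose
per-class probabilities.

**Boosted trees on object counts.** XGBoost multiclass
(`multi:softprob`, 300 rounds cap, depth 5, learning rate 0.1,
single-threaded, seeded) with early stopping once 5 rounds bring no
improvement in validation class-prediction error. Classes absent from
training receive zero probability; predictions are reported on the full
scheme. Hyperparameters are fixed documented defaults rather than a
search, trading a little accuracy for determinism and desk-scale
runtime.

**Small convolutional network on frames.** Implemented directly on numpy
(im2col convolutions with manual backpropagation): two stride-2 blocks
(5×5, 8 channels; 3×3, 16 channels; ReLU) and a dense softmax head,
He-initialised, on 32×32 inputs (frames are bilinearly resized).
Training is SGD with momentum 0.9, batch 32; the default learning rate
0.01 and 10–15 epochs suit this small network (the full-scale recipe's
0.001 is retained in the config surface and can be restored). The
returned model is the epoch snapshot with the best validation exact
accuracy. Training-time augmentation: uniform border crops always
preserving the central 90% image area, rotations uniform in ±10°, and
horizontal flips with probability ½; per-channel Z-score normalisation
uses training-set statistics, reused verbatim at validation/test time
(global per-channel statistics, not per-site). All randomness flows from
the config seed; runs are bit-reproducible single-threaded. Gradients
are verified against finite differences in the test suite.

**Ordinal loss.** Cross-entropy plus a unimodality penalty:

    L(p, y) = −log p_y + λ · Σ_{k} φ_t(z_k)

where the K−1 adjacent-pair gaps `z_k = p_k − p_{k+1}` for k < y and
`z_k = p_{k+1} − p_k` for k ≥ y are all ≤ 0 exactly when the probability
profile rises to the true class and falls after it, and φ_t is the
smooth log-barrier extension

    φ_t(z) = −(1/t)·log(−z)                    if z ≤ −1/t²
             t·z − (1/t)·log(1/t²) + 1/t       otherwise,

convex and C¹, finite on the whole simplex, with φ_t → 0 on strictly
satisfied constraints as t grows. Defaults λ = 0.1, fixed t = 5 (no
annealing). With λ = 0 the loss is exactly cross-entropy (tested to
machine precision), and any unimodality violation costs strictly more
than its monotone rearrangement at fixed `p_y`. The barrier form and the
adjacent-pair constraint set are isolated behind the `ordinal_loss`
interface so alternative formulations can be swapped in.

## Evaluation

* **Accuracy.** Exact and ±1-class (prediction in the true or an
  adjacent class).
* **Null models.** The default *marginal-draw* null is the expected
  accuracy of sampling predictions from the training class distribution,
  computed in closed form: `Σ_c p_train(c)·p_test(c)`, and
  `p_train^T K p_test` with the `|i−j| ≤ 1` kernel for the ±1 analogue
  (verified against 100,000-draw simulation). A *modal* null (always
  predict the training modal class) is retained for sensitivity.
* **Similarity.** Bhattacharyya coefficient `Σ_c √(p_c q_c)` between
  train and test class distributions.
* **Stratification.** Day/night, Harmattan/non-Harmattan and land-use
  accuracies with per-stratum nulls; empty strata report n = 0 rather
  than failing.
* **2c comparison.** Paired difference in exact accuracy on the shared
  test set, annotated with a seeded 1,000-resample paired bootstrap
  interval (an uncertainty annotation only; point estimates are the
  primary quantities).

## Attribution

* **Permutation importance**: drop in test exact accuracy after
  shuffling one count column, averaged over R = 10 seeded shuffles (a
  single shuffle is noisy; the SD across repetitions is reported).
  Negative values are reported as-is. When count columns correlate above
  0.8 the report carries a collinearity warning: correlated objects
  share importance, so per-object scores are deflated — flagged, not
  corrected.
* **Object–pollution correlations**: per site and category, Spearman ρ
  between counts and the continuous pollution value (average ranks on
  ties; zero-variance columns reported missing; sites under 30 usable
  records skipped).
* **Explained-variance linkage**: squared Pearson correlation between
  the per-category correlation and importance vectors.
* **Pixel features**: day frames use RGB channel means; night frames use
  grayscale (channel-mean) mean and SD. The Harmattan summary reports
  per-site Harmattan minus non-Harmattan deltas and per-site Spearman
  correlations of each feature with PM2.5, averaged *unweighted* across
  sites (a reporting convention; sites contribute equally).

## Problem sizes used in tests and the acceptance script

Worlds are scaled per experiment, chosen once as the package's study
conditions:

* Same-site (1a): one fixed site, 10 recording days (~5,100 records);
  CNN trained 10 epochs. GBM is checked on noise and the CNN on PM2.5 —
  each family's stronger planted channel (counts carry the activity
  signal that drives noise; the tint/haze encode PM2.5).
* Cross-site (1b): five fixed sites, 4 recording days, site-baseline SD
  5 dBA; the GBM family.
* Allocation (2c): 4 fixed sites × 15 days versus 30 rotating sites ×
  1 day (the few-sites arm trains on ≈3× the records), site-baseline SD
  5 dBA so that site heterogeneity — the mechanism behind the
  diversity-beats-volume result — is materially present.
* Attribution: one fixed site, 20 recording days, equal base rates
  `a_o = −0.5` with couplings `b_o` spread linearly 0.3–2.0 across the
  16 retained categories, reduced noise error (0.75 dBA) and uniform
  day/night visibility. The last choice matters: a shared visibility
  factor adds a second common driver of all counts, which inflates
  feature redundancy and degrades the monotone link between planted
  `b_o` and permutation importance (the collinearity caveat above, in
  action).

## What passing tests show — and what they don't

The synthetic world plants exactly the structure the analysis assumes:
activity-driven counts and noise, a visually encoded PM2.5, site random
effects. Passing tests therefore demonstrate that the *pipeline*
(pairing, splitting, training, benchmarking, attribution) recovers known
structure correctly and reproduces the qualitative findings — models
beating distribution-only nulls at single sites, degradation across
sites tracking distribution overlap, spatial diversity beating data
volume, object effects and haze signatures recoverable. They do not
validate the generator's realism: real street scenes, detector errors,
meteorology and source mixes are far richer, and absolute accuracies
here do not transfer to any real campaign.

Known limitations: rectangles-for-objects rendering; a single shared
activity latent (real object categories have partially independent
drivers); fixed-clock day/night; no weather covariates; detector
emulation by ground-truth counts with optional Poisson thinning
(recall), not a learned detector; CNN determinism guaranteed only
single-threaded.
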