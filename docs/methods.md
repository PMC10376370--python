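# Methods

## Data model

A sample is a continuous-mode ion-image dataset: a list of integer spot
coordinates, one strictly increasing m/z axis shared by every spot, and a
nonnegative `[n_spots × n_channels]` intensity matrix, with diet group
(CTRL / HFHS), feeding time point (3 d … 16 w) and ionization mode as
metadata (JSON sidecar next to the imzML file, since imzML has no standard
slot for them). Processed-mode imzML (per-spot axes) is rejected rather than
resampled: every downstream stage — baseline correction, mean-spectrum peak
picking, interval features — assumes the shared axis.

## Preprocessing

Order is fixed and load-bearing: **mass filters → Tophat → TIC**.

1. *Mass filters.* Channels below m/z 400 are removed (the instrument
   deflects them), as is the matrix-cluster window. The artifact interval is
   described by its center (m/z 500) and total width (14), which we read as
   [493, 507]; centering is an interpretation, recorded here, since only
   center and size are stated.
2. *Tophat baseline correction* subtracts the morphological opening (flat
   structuring element) from each spot spectrum; output is nonnegative and
   elementwise ≤ input. The element width default is 31 channels ≈ 5× the
   FWHM of the synthetic peaks at 0.1 Th spacing — wide enough to pass under
   peaks, narrow enough to track baseline drift. Widths must be odd and ≥ 3.
3. *TIC normalization* rescales each spot to unit channel sum (or to the
   pre-normalization mean TIC). Excluding the matrix window *before*
   normalizing keeps matrix signal out of the per-spot scale. Zero-TIC spots
   cannot be normalized and are dropped with a logged warning, never imputed.

Because smoothing is deliberately out of scope, the opening of a *noisy*
spectrum sits roughly 2σ below the local signal level, so correction leaves a
small positive noise pedestal in every channel. At the default noise level
this pedestal is small relative to peak areas; it is a known artifact of
morphological baseline removal without prior smoothing.

## Peak detection (OMP)

Detection runs once per (time point, mode) batch on the pooled mean spectrum
of all the batch's samples — all sections of a time point are processed and
analysed together. The dictionary holds one unit-norm Gaussian atom (width
σ, default 0.25 Th, support ±4σ) per channel, built from true m/z
differences so gaps left by excluded windows are handled. Greedy loop:

- select the atom maximally correlated with the residual;
- refine its center to sub-channel precision: locate the apex within ±σ and
  apply three-point log-parabolic interpolation (exact for a sampled
  Gaussian; falls back to the intensity-weighted centroid) — this is the
  centroid-matching alignment step, applied inside the loop so an off-grid
  peak is modeled by a single atom instead of a stack of flank atoms;
- rebuild the atom at the refined center, refit all selected coefficients by
  least squares (incremental Cholesky on the Gram matrix, so 500-atom runs
  stay cheap), update the residual.

Stopping: relative residual ≤ `residual_tol` (default 0.02), or `max_peaks`
(default 500) atoms, or the best remaining correlation falls below
`residual_tol · ‖spectrum‖` (an atom below that floor cannot reach the
tolerance). Channels within 3σ of a selected center are blocked from later
selection — the same radius as the aggregation interval half-width, so peak
intervals cannot collide; peaks closer than that are not resolved at this
atom width. Atoms whose refit coefficient ends non-positive are discarded.
Residual norms per iteration are kept in the result's provenance (they are
non-increasing; tests assert it).

Feature extraction: intervals are [center ± 3σ], truncated at midpoints
between neighbours. Per spot and peak, the local maximum inside the interval
is located, the intensity-weighted centroid in a ±σ window around it is
computed, and the summed interval intensity is recorded if the centroid
falls inside the interval, else 0. Aggregation by interval sum (not max) is
a documented choice. Skyline spectra are per-channel maxima over one group's
spots.

## Spatial segmentation

Bisecting k-means under the Manhattan metric: starting from one cluster, the
leaf with the largest total L1 dispersion about its component-wise median is
split by 2-means alternating minimization — L1 assignment, component-wise
*median* centers (the minimizer of L1 dispersion, keeping the objective
internally consistent) — best of 5 random initializations, for `depth` splits
(default 2 → background / stroma / epithelium). Initial centers are drawn
through a canonical lexicographic row order, making results invariant to
spot ordering at a fixed seed. The original workflow chose depth
interactively; here depth is a config integer and the per-split dispersions
are reported so a user can judge it.

Segmentation runs per sample on the feature table (not raw channels) for
tractability, restricted to the `top_k` (default 100) most intense peaks: a
generous OMP budget admits atoms modelling residual noise, and keeping only
the strong peaks prevents those noise-level features from diluting the
tissue signature. The epithelial ROI is the leaf with the best Dice overlap
against the user-supplied reference mask (the explicit stand-in for H&E
co-registration); best Dice < 0.2 is an error, not a silent fallback.

## Discriminative-mass calling

For each peak, epithelium-spot intensities are pooled across the replicates
of each group and compared by ROC AUC computed from rank statistics
(Mann–Whitney; ties half-credited). Calling at threshold T = 0.7:
HFHS-vs-CTRL if AUC ≥ T, CTRL-vs-HFHS if 1 − AUC ≥ T; with T > 0.5 at most
one direction fires per peak. Two deliberate properties inherited from the
source workflow, stated prominently:

- **no multiple-testing correction** — calling is by AUC threshold alone;
- **pseudoreplication** — spots are pooled across the 3 animals per group,
  so the effective null AUC spread is wider than the iid Mann–Whitney SE
  (replicate-level amplitude variation acts as a cluster effect). A
  per-animal-mean alternative (`pool_samples=False`) avoids this at the cost
  of n = 3 per group.

Cross-time-point overlap uses greedy nearest-m/z pairing within 0.1 Th,
same mode only, each DM matched at most once.

## Annotation

The lipid database is generated from formula rules (n = total acyl carbons,
d = double bonds): PC C(n+8)H(2n−2d+16)NO8P, PE C(n+5)H(2n−2d+10)NO8P,
PS C(n+6)H(2n−2d+10)NO10P, PI C(n+9)H(2n−2d+15)O13P,
SM C(n+5)H(2n−2d+13)N2O6P; lyso forms add H2 and drop one O. Monoisotopic
masses come from standard atomic masses (recomputable to 1e-4 Da; tests pin
reference species such as PC(34:1) = C42H82NO8P, 759.5778 Da). Diacyl
species span carbons 28–44, double bonds 0–8; lyso 14–22 / 0–4. Adducts:
{+H, +Na, +K} in positive mode, {−H} in negative (proton/electron masses
included); tolerance 0.05 Da (TOF-scale), configurable. All matches within
tolerance are reported; the category joins the sorted unique candidate
classes ("PC/PE"), or "unassigned". Identification is mass-only by design —
no MS/MS — so every assignment is putative.

## Synthetic-study generator

The generator emulates the study's structure so recovery is scoreable:

- *Geometry*: a 20×20 spot grid; stromal disk (radius 0.225·grid), epithelial
  ring (to 0.375·grid, ≈112 spots), matrix background outside — a tubular
  organ's cross section.
- *Peaks*: 80 per mode layout, 70% drawn as lipid-DB species + adduct (exact
  theoretical m/z, so end-to-end annotation has recoverable truth), 6 random
  unassignable masses at 1400–1600, the rest random, mass-weighted toward
  700–900; minimum center separation 2 Th. Region affinity per peak:
  epithelium-dominant, stroma-dominant (minor weight 0.2 elsewhere) or
  shared, with background weight 0.03. A matrix artifact peak (amplitude
  400) sits at exactly m/z 500 in *all* regions to exercise the exclusion
  window.
- *Spot model*: `tic_mult × (Σ amplitude·weight·Gaussian(σ=0.25 Th) +
  baseline) + noise`, clipped at 0. Baseline: monotone-cubic interpolation
  of 8 positive random knots, ~20% of the reference peak height (100), drawn
  per sample so Tophat has real work. TIC multipliers: lognormal, σ = 0.15.
  Noise: additive Gaussian (σ = 8, i.e. 8% of the reference height; spot
  peak-area CVs come out ≈10–30%, noisy single-pixel TOF territory),
  truncated at zero — a simpler stand-in for count noise, sufficient for
  rank-based ROC. Replicates differ by fresh noise/TIC draws plus 5%
  lognormal per-peak amplitude jitter.
- *Planted DRLs*: 3 up (fold 2.0) and 5 down (fold 0.4) epithelium-dominant
  lipid-derived peaks at the common reference amplitude, applied to HFHS
  epithelium. The 3·(2.0−1) = 5·(1−0.4) balance keeps total epithelial
  signal (hence per-spot TIC) unchanged in expectation: TIC renormalization
  otherwise leaks a systematic shift into every null feature. That leakage
  is real and faithful to TIC normalization — configure unbalanced folds to
  observe it — but a calibration dataset should not bake it into the null.

Determinism: one `numpy` Generator seeded once; identical (config, seed) ⇒
bit-identical datasets. The manifest records regions, every planted peak
(m/z, amplitude, weights, species), every DRL (direction, fold), and the
noise/baseline/TIC parameters.

What the generator does **not** emulate — so what passing tests do not show
about real data: isotope envelopes and peak-shape dependence on m/z,
detector saturation, count-noise statistics, spatial intensity gradients and
section-to-section geometry differences, chimeric/overlapping peaks, and
real matrix chemical noise beyond one artifact peak. Recovery rates here are
upper bounds for data with those complications.

## Problem sizes

Tests and the acceptance script run the default single-batch study (one time
point, positive mode, 2 groups × 3 samples × 400 spots × 16001 channels)
over seeds 1–5; the null calibration uses 16×16 grids with ≈240 planted null
peaks; narrow-window configurations (m/z 700–800, 12×12) serve the unit
tests. These sizes give stable recovery statistics while keeping a full
verification run in minutes on one CPU; the full 6-time-point × 2-mode
design is available through `StudyDesign`.

## Known limitations

- AUC-threshold calling without error control: the DM list's false-positive
  content depends on spot counts and cluster effects; the null-calibration
  test quantifies it on synthetic data only.
- The noise pedestal left by smoothing-free Tophat slightly compresses
  fold-change ratios of interval features (it cancels nowhere); direction
  and ranking, which drive the ROC, are unaffected.
- Mass-only annotation cannot separate isobars beyond listing them in one
  category; the packaged DB covers 9 phospholipid/sphingolipid classes and
  no ether/oxidized species, so masses at 1400–1600 stay "unassigned".
- Dice-based ROI selection presumes the reference mask and the section share
  coordinates exactly; no image registration is attempted.
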