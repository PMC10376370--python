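# ovimsi

MALDI mass-spectrometry-imaging (MSI) analysis of diet-induced lipid
remodelling in the oviductal epithelium.

## The problem

Feeding mice a high-fat/high-sugar (HF/HS) diet changes the lipid composition
of the oviductal epithelium (OE) — the cell layer that hosts early embryo
development — progressively over weeks of feeding. MALDI-MSI measures a full
mass spectrum (m/z 400–2000, positive and negative reflectron modes) at every
spot of a tissue-section raster, so each lipid ion yields an image. The
analytical challenge is to (1) isolate the thin epithelial cell layer from
stroma and off-tissue background without manual outlining, (2) decide which
m/z values discriminate the diet groups, in *both* directions of change, and
(3) attach putative lipid-class labels to those masses.

`ovimsi` implements that workflow end to end for continuous-mode imzML data:

- **preprocess** — crop to the acquisition window, excise the matrix-cluster
  artifact at m/z 500 ± 7, Tophat (morphological-opening) baseline correction,
  total-ion-count (TIC) normalization per spot;
- **peaks** — orthogonal matching pursuit (OMP) over Gaussian atoms on the
  batch mean spectrum, centroid alignment, per-spot interval features,
  skyline projection spectra;
- **segmentation** — bisecting k-means under the Manhattan (L1) metric with
  component-wise-median centers; epithelium ROI selected by Dice overlap with
  a reference mask (the stand-in for H&E co-registration);
- **diff** — per-peak ROC analysis of pooled ROI spectra. The AUC estimates
  P(HF/HS spot > CTRL spot), ties half-credited (Mann–Whitney); a mass is a
  *discriminative mass* (DM) when AUC ≥ 0.7 in either direction
  (HF/HS vs CTRL ⇒ higher under the diet; CTRL vs HF/HS ⇒ lower);
- **annotation** — formula-derived monoisotopic masses for PC, PE, PS, PI,
  SM and their lyso forms (e.g. PC *n*:*d* = C(n+8)H(2n−2d+16)NO8P), matched
  as [M+H]⁺/[M+Na]⁺/[M+K]⁺ or [M−H]⁻ within 0.05 Da, with ambiguity reported
  as joined categories ("PC/PE");
- **synth** — a synthetic-study generator (ring-shaped epithelium, stroma
  core, matrix background; planted differentially regulated lipids in both
  directions; baseline drift, TIC variation, noise) with a ground-truth
  manifest, so every stage is testable without any data download.

Because no raw MSI data are publicly deposited for this study design, all
quantitative verification runs on synthetic data with planted truth, plus
arithmetic worked examples on published summary numbers.

## Worked example

`analysis/` contains the numbered study drivers. Running them in order
simulates a two-time-point study (3 d and 16 w, positive mode, 3 mice per
diet group, 20×20 spots) and analyses it:

```bash
python analysis/01_simulate_study.py
python analysis/02_preprocess_and_peaks.py
python analysis/03_segment_epithelium.py
python analysis/04_discriminative_masses.py
python analysis/05_annotate_lipids.py
python analysis/06_summary_statistics.py
```

Output excerpts (seed 1):

```
batch 16w/positive: 500 peaks detected, 79/80 planted peaks recovered
min ARI 1.000, min ROI Dice 1.000 across 12 sections
batch 16w/positive: 8 DMs called; sensitivity 1.00, false calls 0
batch 3d/positive: 9 DMs called; sensitivity 1.00, false calls 1
16/17 DMs putatively annotated (94.1%)
16/16 recovered planted DRLs annotated with their true class
```

Reading: peak detection recovers 79 of the 80 planted peaks (the missing one
sits inside the excluded matrix window, as intended); depth-2 segmentation
reproduces the planted epithelium/stroma/background partition exactly (ARI,
the adjusted Rand index, is 1) and the selected ROI matches the reference
mask (Dice 1); ROC calling at AUC ≥ 0.7 recovers all 8 planted fold-2 lipid
changes per batch with one spurious call; and every recovered planted lipid
receives a category containing its true class. The summary-statistics driver
prints the published worked numbers: a 33.6% body-weight difference at 12 w
(48.30 g vs 36.16 g), DM totals rising from 11 (3 d) to 227 (16 w), and PI
proportions of 28.6% vs 19.5% between ROC directions.

The same pipeline is scriptable from a shell (`ovimsi simulate / run / roc /
annotate`) or driven by one YAML config via `ovimsi.pipeline.run_study`.

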