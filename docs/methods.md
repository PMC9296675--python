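# Methods

This note documents the models behind `pimohet`, the parameters that
matter, the numerical choices, and what the synthetic-data validation does
and does not establish.

## 1. Synthetic cohort model (`synthgen`)

The generator emulates a prostatectomy hypoxia study: per patient one
whole-mount section with a circular index lesion, one or two 6 mm punch
biopsies from that lesion, ordinal pathologist hypoxia scores (two raters),
probe-level log2 expression in two extraction-kit batches, clinical markers
and exponential survival. All randomness derives from one root seed through
named `SeedSequence` streams (truth, field, stain, scores, expression,
clinical, survival), with per-patient child streams for the field and stain
so single patients can be re-rendered independently and reproducibly.

### Spatial hypoxia field

True whole-mount hypoxic fractions are drawn from `Beta(2, b)` with `b`
set in closed form so the theoretical median equals
`target_median_hf` (default 0.27, the emulated cohort's median). Within
the lesion a standardised field

    H = (z_micro + w * z_coarse) / sqrt(1 + w^2),   w = 5 * within_lesion_sd

combines a *stratified* fine-grained component (a jittered 16×16
ordered-dither pattern mapped through the normal quantile function — every
punch-sized disk samples the full marginal, so at `w = 0` any biopsy is
exactly representative of its lesion) with a smoothed Gaussian random
field of correlation length `spatial_corr_length_px` (sigma = half the
correlation length). A pixel is truly hypoxic iff `H` exceeds the
per-patient cut placed at the empirical `(1 − HF)` quantile of `H` over
the lesion, so the planted whole-mount HF is exact up to pixel
discreteness. Biopsy truth values are the hypoxic fractions over the punch
disks (uniform non-overlapping placement inside the lesion; placement
restarts after a run of rejections because a centrally placed first punch
can make a second one geometrically impossible). The factor 5 in `w` makes
`within_lesion_sd` approximately the standard deviation of biopsy HF
around whole-mount HF at mid-range HF; it is a convenience calibration,
not a fitted constant.

The spatial statistics of real pimonidazole staining are not described in
the literature this emulates; the random-field model is a stand-in chosen
to reproduce patchy staining with two knobs, not a biological claim.

### Stain model

DAB optical density inside the lesion is

    OD = t* + amp_s * (H − cut) + noise,  amp_s = scale_s * (od_hyp − od_bg) / 2

with `t*` the generating segmentation threshold (midpoint of
`od_hypoxic_mean` = 0.8 and `od_background_mean` = 0.2, i.e. 0.5),
per-section amplitude factor `scale_s ~ U(0.4, 2.0)` (staining-batch
variation) and pixel noise sd `od_noise_sd` = 0.02. Because the amplitude
pivots at `t*`, a pixel is stained above threshold exactly when it is truly
hypoxic, for any amplitude. Haematoxylin counterstain (OD 0.30) covers all
tissue; RGB is produced through the standard haematoxylin/DAB stain matrix
and 8-bit quantisation. Whole-mount sections are rendered at 192 px and
~200 µm/pixel — a heavily down-sampled stand-in for slide scans; only
stain-intensity structure matters downstream, not histomorphology.

The amplitude heterogeneity is load-bearing: a threshold calibrated by
*rank* correlation against ordinal scores is only identifiable if sections
differ in the shape of their OD distributions. With a common amplitude,
every candidate threshold ranks sections identically and the objective is
flat over a wide plateau. The defaults were fixed by this identifiability
analysis (and verified on held-out seeds) so that the calibration recovers
`t*` to within one grid step on 40-section cohorts.

### Scores, expression, outcomes

*Pathologist scores*: the true score is the quintile bin of the section's
true HF within its section-kind group; each rater independently misreads
by ±1 with probability `score_noise`, clipped to 1–5. The default 0.085
was set in closed form so two raters agree with Cohen's kappa ≈ 0.80
(`po = (1−p)² + p²/2`, `pe = 0.2`), a typical inter-observer agreement for experienced raters
on this kind of ordinal scale.

*Expression*: the latent hypoxia driving a biopsy's expression is the
z-score of `(1 − local_fraction) · HF_wholemount + local_fraction ·
HF_biopsy` (default `local_fraction = 0.3`). This encodes that the
signature reflects a persistent, largely lesion-wide transcriptional
programme with a modest local component — the property that makes a
multi-gene score reproducible across biopsies even when pimonidazole
staining is patchy. Signature-gene probes are shifted by `effect_size`
(0.5 log2 units) per latent unit; probe noise sd is 0.5 log2; every 10th
gene carries two probes and every 40th a third, with their own offsets and
noise scales, to exercise the IQR collapse; kit-A samples (fraction
45/141) are offset by `kit_offset` on every probe. `n_genes` defaults to
2000, a scaled-down stand-in for a ~47k-transcript array — nothing
downstream depends on the absolute count.

*Clinical and survival*: lymph-node status is Bernoulli with logistic link
on z-scored true HF; ISUP (1–5) and pT (2–4) come from ordered Gaussian
latents with cut points matching the emulated cohort's marginals (8/42/
24/15/11% and 32/67/1%); survival is exponential with log-hazard
`log(baseline_rate) + log_hr_per_unit_score · score`, independent
exponential censoring and an administrative follow-up cap (defaults:
baseline 0.05/yr, HR 2 per score unit, censoring 0.03/yr, 10 yr cap).
Weibull baselines are left as a configuration extension.

## 2. Image quantification (`histoquant`)

- **White level**: per-channel 99th percentile of near-white pixels
  (fallback: global 99th percentile for crops without background).
- **Tissue mask**: mean-channel intensity below 92% of the white level; no
  morphology by default (an optional median filter exists but is off).
- **Stain separation**: per-channel OD projected onto the published
  haematoxylin/DAB basis; the DAB component is the pimonidazole signal.
  Stain vectors are never estimated from data.
- **Threshold calibration**: grid search maximising Spearman correlation
  between per-section HF and mean-over-raters score; one threshold per
  protocol (whole-mount and biopsy sections are stained separately and are
  calibrated and stored independently). The grid spans the 1st–99th
  percentile of pooled in-region OD with 60 candidates by default: the
  measured resolving power of the rank objective is ~0.007 OD regardless
  of grid density (knife-edge section pairs at score-bin boundaries set a
  floor), so the default step (~2.5× that spread) makes "one grid step" an
  honest statement of precision. Because ordinal scores produce a plateau
  of equally optimal thresholds, the **plateau midpoint** is returned
  (rounding toward the lower grid point on exact half-ties); the plateau's
  lower edge was measured to be a systematically low estimate.
- **Lesion masks are supplied, never inferred** — index lesions are
  outlined manually in practice.

The segmentation procedure is a from-scratch design, not a
reimplementation of any proprietary digital-pathology platform; its
choices are validated by generator round-trip (planted-HF recovery, MAE ≤ 0.05 over 40
sections) rather than by comparison with the original implementation.

## 3. Gene score (`sigscore`)

Optional quantile normalisation (mean order statistics, rank ties averaged)
→ kit harmonisation (per probe, kit-A values shifted by the difference of
kit medians; the miRNeasy-like kit B is the untouched reference; the
operation is idempotent) → probe collapse (largest across-sample IQR, 25th
to 75th percentile with linear interpolation; ties break to the
lexicographically smallest probe id, so the collapse is deterministic under
probe reordering) → score = mean over signature genes of median-centred
log2 expression.

Centring medians are computed over **all samples of the supplied matrix**
(the full analysis cohort, including both biopsies of paired patients);
external cohorts are centred within themselves. The cohort id is recorded
in the output to prevent cross-cohort mixing. Whether centring should use
all biopsies or one per patient is genuinely ambiguous for paired-biopsy
designs; all-samples is the default and the choice is a function argument.
By default every signature gene must be present; `min_fraction` relaxes
this, with missing genes listed in the output. Linear-scale input must be
declared explicitly (`from_linear`); silent auto-detection is deliberately
not offered. The bundled 32-gene file is a synthetic stand-in naming the
generator's planted genes; real signatures are supplied as text files.

## 4. Heterogeneity (`heterogeneity`)

Relative difference uses the overall range of exactly the biopsies entering
the current comparison (both members of every pair), not the full cohort.
The difference is unsigned by default. The ordered-pair correlation (max vs
min) is invariant to within-pair label swaps but *inflated* relative to a
random pair ordering; the summary carries a note saying so, because the
emulated analysis design plots exactly this quantity. P-values for ordered-pair r
treat pairs as independent observations and inherit that ordering bias.

## 5. Concordance (`concordance`)

- Percentile cut-offs use linear interpolation of order statistics (the
  numpy default); the convention is fixed and tested because the
  67th-percentile classification depends on it.
- Ties at the cut-off: strictly greater ⇒ "more hypoxic".
- The reference population for a cut-off may differ from the classified
  subset (e.g. median from all patients, applied to the subset with all
  three assays); the three-way overlap is computed on the intersection of
  patients with an explicit exclusion list.
- Mann-Whitney: exact enumeration for n1+n2 ≤ 12 without ties, otherwise
  the normal approximation with tie and continuity correction.
- Benjamini–Hochberg: the default "paper" variant is the per-rank
  `min(1, p·m/rank)` without the step-up monotonicity pass (tied p-values
  share the largest rank); the standard step-up variant is available and
  the variant used is recorded in every output. The per-rank variant can
  produce adjusted values that violate monotonicity — that behaviour is
  intentional and tested, since it is the only variant consistent with the
  printed values this package reproduces in its worked-example tests.
- BH families: one family per measured variable = the three
  clinical-marker tests for that variable.

## 6. Prognosis (`prognosis`)

Cox models use lifelines (Efron tie handling, Wald CIs and p-values);
multivariate fits additionally report whether forward and backward Wald-p
stepwise selection at α = 0.05 select the same covariates. Kaplan–Meier
estimates come with at-risk tables for plotting; the log-rank test is
checked in the test suite against a from-first-principles oracle that is
simultaneously the score test of a Cox fit on the group indicator. The
cut-off scan walks a percentile grid (default every 5th percentile from 10
to 90; "all distinct values" is configurable but bounded output is the
default), skips cut-offs leaving fewer than 5 subjects in a group, and
flags — rather than corrects — the optimism of minimum-p selection, since
the emulated analysis design makes the same selection without correction.

## 7. What a green test establishes — and what it does not

The synthetic generator provides *parameter recovery* targets: planted HF
recovered from rendered images (MAE ≤ 0.05; threshold within one grid
step), planted expression effects recovered as score-latent correlation
≥ 0.8, planted hazard ratios recovered by Cox fits (mean within ±10%), and
the qualitative heterogeneity contrast (HF more heterogeneous than the
score under high within-lesion variance and low gene noise). These
demonstrate that the pipeline's arithmetic and wiring are correct, not
that the models describe real tissue: the generator has circular lesions,
two-component Gaussian fields, linear stain response, symmetric rater
errors and exponential hazards — none of which real cohorts honour.
Reproducing any specific real cohort's headline numbers (particular
correlations, agreement percentages, hazard ratios) would require the
corresponding images and a published gene list and is deliberately out of
the validation scope; the statistics-level worked examples (the BH
adjusted values) are reproduced exactly from fixed reference inputs.

## 8. Degenerate inputs and failure behaviour

Every contract failure raises a typed exception (`ConfigurationError`
naming the offending field, `DegenerateDataError` for zero ranges or
constant covariates, `AlignmentError` with the mismatching ids,
`CoverageError` naming missing signature genes, and so on); the pipeline
driver aborts with the failing stage named, preserving partial outputs.
Biopsies without inclusion annotations are excluded with an explicit
"unannotated" reason, never silently kept.
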