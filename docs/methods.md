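# Methods

## The cumulative-methylation score

`ctmeth` scores two-cartridge methylation-specific qPCR runs of a 9-gene
circulating-tumor-DNA panel (HOXB4, RASGRF2, AKR1B1, TM6SF1, COL6A2,
HIST1H3C, TMEFF2, RASSF1, ZNF671) with ACTB as the endogenous total-cfDNA
reference in both detection cartridges (A carries 4 targets, B carries 5).
The per-sample score is computed in four steps:

1. **Normalization.** Undetected reactions are assigned the sentinel
   Ct = 45. Each target's ΔCt = Ct_gene − Ct_ACTB is formed against the ACTB
   of the *same* cartridge. If any gene's ΔCt falls below 1 anywhere in the
   analysis batch, the smallest nonnegative integer k with min(ΔCt) + k ≥ 1
   is added to every sample for that gene. Targeting 1 rather than an
   arbitrary positive value bounds per-gene methylation at M ≤ 1200 and
   prevents explosive scores from near-zero ΔCt.
2. **Censoring.** A ΔCt strictly above the gene's censoring bound — the
   historical replicate median ΔCt at 300 spiked copies, plus 13 cycles —
   is set to 0. Thirteen doublings below 300 copies is 300 × 2⁻¹³ ≈ 0.037
   copies, i.e. the bound removes signals below a ~0.04-copy quantitation
   floor. The same shift constant k is added to the gene's calibration
   median before the comparison, so the censoring decision is identical on
   the raw and shifted scales (property-tested). Equality at the bound is
   retained; only strictly higher values are censored.
3. **Per-gene methylation.** M = 1200 / ΔCt for quantifiable genes; a
   censored gene contributes M = 0 (the 0 sentinel is "removed from the
   analysis", never divided).
4. **Cumulative methylation.** CM = Σ M over the 9 targets. A sample whose
   ACTB is undetected in either cartridge is invalidated rather than scored
   from the surviving cartridge, because CM is defined over all 9 genes.

A sample is called positive when CM is **strictly greater than** the locked
threshold (default 38.5 CM units). The source assay's documentation is
ambiguous between ">" and "≥" at the cutoff; we implement strict ">" and
note that the two differ only for scores exactly on the boundary, a
measure-zero event for continuous CM.

### Calibration

`build_calibration` takes ≥ 3 replicate runs of 300 spiked copies and
records the per-gene median raw ΔCt (mean of the middle pair for even
counts). Shift constants start at 0 and are filled in per analysis batch by
`score_batch`. Calibration files are keyed per matrix by the caller if
desired; a single table is the shipped default since the historical medians
are not published per matrix. Replicate quality is summarized by CV% =
100 · sd(n−1) / mean of CM across replicates.

## Statistical evaluation

* **Group comparison** — Mann–Whitney U with average ranks for ties. For
  tie-free pooled samples of ≤ 12 observations the two-sided p is exact by
  enumeration of all rank assignments; otherwise a normal approximation
  with tie and continuity corrections is used. The boundary is fixed and
  tested on both sides.
* **ROC** — AUC is the concordant-pair fraction with ties counted ½
  (identically U/(n₁n₂), asserted as a cross-implementation invariant).
  Candidate thresholds are midpoints of consecutive distinct scores plus
  ±∞; the derived threshold maximizes Youden's J, ties broken toward higher
  specificity and then the larger cutoff. The AUC confidence interval is
  DeLong's, clipped to [0, 1].
* **Confusion metrics** — sensitivity, specificity and accuracy carry
  Wilson score 95% intervals (a standard choice; the exact CI flavor of the
  original analysis software is not documented). LR+ = sens/(1 − spec) is
  flagged undefined when specificity is exactly 1.
* **Concordance** — Spearman rank correlation (average ranks), two-sided p
  via the t-approximation, for interuser and interplatform comparisons.
* **Cohorts** — benign and normal samples are pooled as the control class.
  Training mode derives the threshold from the cohort itself; test mode
  evaluates at a supplied locked threshold.
* **Trajectories** — serial draws are sorted by day, deltas taken from the
  baseline (earliest) draw, and each interval labelled rise/fall/flat with
  a configurable dead band (default 5 CM units). No formal progression rule
  is implied; the labels are descriptive.

## The synthetic generator

Patient-level data behind the assay's published validation are not publicly
deposited, so every analysis here runs on synthetic Ct tables whose
statistical structure mirrors the study designs.

The measurement model is the simplest one consistent with the algorithm's
own arithmetic: a reaction with expected template copies λ draws
k ~ Poisson(λ); k = 0 is a no-signal reaction (Ct 45); otherwise
Ct = α_g − log₂(k) + N(0, σ) — ideal one-cycle-per-doubling kinetics with
Gaussian instrument noise and no efficiency parameter. The 20-cycle nested
preamplification is folded into the per-gene intercept α_g (only final Ct
matters downstream). A sample splits equally across the two detection
cartridges, halving the copies each cartridge sees; ACTB reflects a shared
sample-level cfDNA load measured once per cartridge, which induces the
within-cartridge correlation real runs show.

Key defaults and why:

* **Intercepts** α_g ≈ 33 for targets, 38 for ACTB. This puts 300-copy
  calibration medians at 2.7–3.4 ΔCt, so every censoring bound
  (median + 13 ≈ 16) sits below 45 − max ACTB Ct (≈ 17.2). That ordering is
  a consistency requirement of the algorithm itself: it guarantees a
  no-signal reaction is always censored rather than scored, which is what
  makes real control samples score exactly CM = 0 (as the published control
  quartiles do). ACTB at 2¹⁵ background copies per cartridge lands near
  Ct 23, mid-range for normal samples.
* **Ct noise** σ = 0.30 cycles (plasma) and 1.00 (serum). These were
  calibrated once so the replicate CM CV at 300 copies centers inside the
  observed bands — 7.1–10.9% in plasma, 19.0–36.1% in serum. Note that a CV
  estimated from 11 replicates has a relative sampling sd of ≥
  √(1/(2·10)) ≈ 22% whatever the truth, so individual batch CVs scatter
  well beyond the plasma band even with a perfectly centered generator;
  only the serum band is wide enough for most 11-replicate batches to fall
  inside it.
* **Cohorts.** A cancer sample sheds detectable ctDNA with probability
  `detection_rate`; shedding samples activate each gene with probability
  0.6 (≥ 1 forced) and draw per-gene copies from log-normal(ln 150, 1).
  Controls carry low-level background with probability `background_rate`
  (default 0: most real controls score exactly 0). ACTB Ct is uniform
  within the class-specific observed ranges (16.0–27.8 cancer, 21.0–27.4
  normal); only ranges, not distributions, are published. Because any
  detected gene contributes M ≥ ~73 > 38.5, CM is inherently zero-inflated:
  a sample either scores 0 or lands above the positivity threshold — the
  same bimodality the published cohort histograms show.
* **Designed AUC.** With zero background, true AUC = (1 + detection_rate)/2
  exactly (ties at 0 count ½), which `CohortDesign.for_target_auc` inverts.
  Under this zero-inflated design the control placement values are
  degenerate, and the finite-sample coverage of the DeLong interval at
  n = 40/26 is 0.905 by exact enumeration rather than the nominal 0.95 — a
  known behavior of DeLong intervals under heavy ties, reproduced (not
  caused) by this package and asserted against its enumerated value.
* **Interuser duplicates** re-measure each aliquot with extra user-level Ct
  noise, optionally re-drawing molecule counts through the Poisson layer so
  borderline signals can flip to no-signal between users.
* **Longitudinal series** draw at day 0 and before each 21-day cycle; the
  latent burden decays exponentially (half-life 18 days) for response,
  decays to a nadir at the second cycle then regrows for progression, and
  stays constant for stable disease.

All generators require an explicit seed and are pure functions of
(design, seed).

What the generator does **not** model: bisulfite-conversion efficiency,
cfDNA fragment-size effects, amplification efficiency ≠ 2, fluorophore
crosstalk, inter-run drift, or benign-vs-healthy differences in background
methylation (a single knob is exposed instead). Passing tests therefore
demonstrate correctness of the scoring and evaluation machinery under a
faithful statistical emulation, not mechanistic fidelity to any instrument.

## Problem sizes

The shipped test and acceptance runs use the study-shaped sizes throughout:
11 replicates per spike batch; 20 + 20 (training, serum) and 40 + 26 (test,
plasma) cohorts; 15 interuser pairs; 2,000 null simulations for the
type-I-error check; 500 replicate cohorts for DeLong coverage; 150 seed
batches per matrix for the CV-band fraction.

## Known limitations

* The exact Mann–Whitney path enumerates only tie-free pooled samples ≤ 12;
  tied small samples fall back to the corrected normal approximation.
* Scores exactly equal to a censoring bound or the CM threshold follow the
  strict-inequality conventions above; instrument rounding to 0.1 Ct can
  therefore matter at boundaries.
* Wilson intervals and DeLong intervals are method choices; other software
  may print slightly different CIs for the same counts.
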