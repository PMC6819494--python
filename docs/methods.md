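# Methods

## Problem and model

Fine-needle aspiration (FNA) cytology of thyroid nodules leaves roughly a
third of follicular-pattern lesions without a definitive benign/malignant
call.  `thyromir` implements a molecular classification pipeline for such
samples built on a small real-time-PCR marker panel measured on one smear per
sample:

* 13 target miRNAs (miR-144-5p, -145-5p, -155-5p, -146b-5p, -183-5p,
  -199b-5p, -221-3p, -223-3p, -31-5p, -375, -451a, -551b-3p, -7-5p),
  normalized to the geometric mean of three reference miRNAs (miR-197-3p,
  -23a-3p, -29b-3p);
* HMGA2 mRNA normalized to PGK1 mRNA;
* the mitochondrial-to-nuclear DNA copy ratio (mtDNA/nDNA), a Hürthle-cell
  indicator;
* seven somatic driver events (BRAF V600E; HRAS Q61R; NRAS Q61K/Q61R/Q61L;
  RET-PTC1; PAX8-PPARG).

All relative quantities follow the 2^−ΔCq convention.  Because the reference
quantity for the miRNAs is a geometric mean, on the Cq scale it reduces to
the arithmetic mean of the three reference Cq values, so

    log2 level = mean(Cq_ref1, Cq_ref2, Cq_ref3) − Cq_target.

Levels are stored on the log2 scale internally (the mtDNA/nDNA ratio
linearly, since its decision threshold is quoted as a linear copy ratio);
linear values are derived on demand.  This avoids mixing conventions: one of
the published decision thresholds (miR-375 at −12.1213) is only meaningful
on a log scale while the others are linear 2^−ΔCq quantities, so every tree
node carries an explicit `scale` tag and thresholds are converted to the
storage scale at comparison time.

## Classifiers

Two fixed decision trees are shipped verbatim as data structures:

* a **malignancy tree** — HMGA2 ≥ 0.0918 (linear) ⇒ malignant; otherwise
  miR-375 ≥ −12.1213 (log2), then miR-221 ≥ 0.0105, then miR-146b ≥ 1.5362,
  any one elevated ⇒ malignant, else benign;
* a **typing tree** — miR-375 ≥ 5.2514 ⇒ MTC; else miR-146b ≥ 0.1721 ⇒ PTC;
  else mtDNA/nDNA ≥ 5716.3013 ⇒ HCC, else FNMM.

Boundary convention: a value equal to a threshold takes the "≥" branch.
Missing markers are never imputed; a sample missing a marker on its realized
path is reported unclassifiable.

A from-scratch **C4.5-style trainer** re-induces such trees from labelled
marker tables: binary splits of continuous attributes at midpoints between
consecutive sorted distinct values, selected by gain ratio (information gain
over split information) among splits with strictly positive gain, ties broken
toward the smaller threshold.  Defaults: `min_leaf = 5`, pessimistic-error
pruning with confidence factor 0.25 (the classical C4.5 default; the upper
binomial confidence limit is computed from the beta quantile), missing values
excluded at the split (`missing_policy="exclude"`).  The original analysis
software's settings are not documented, so these classical defaults are a
package choice and all are overridable.  The trainer is exposed both as the
function `c45_train` and as the `DecisionTreeModel` / `DecisionTreeResults`
pair (`fit()`, `summary()`, `cross_validate()`).

## Molecular regrouping

Histological labels are remapped to five molecular classes: FVPTC samples
with miR-146b at or above its cutoff are papillary-like (class PTC), the rest
join the follicular neoplasms; follicular neoplasms with HMGA2 or miR-221 or
miR-375 elevated form FNMM, the rest (FNNMM) join goiter as Benign; PTC, MTC
and HCC pass through.  The Results-level notion of "elevated" is not given a
number in the source text, so the defaults reuse the published tree cutoffs
for the same markers (miR-146b 0.1721, HMGA2 0.0918, miR-221 0.0105 linear;
miR-375 −12.1213 log2); all four are configurable (`ReclassThresholds`).

## Evaluation

Sensitivity, specificity, PPV and NPV come from one-vs-rest collapses of a
k×k confusion matrix; undefined ratios are reported as `None`, never 0.
Percentages quoted at whole numbers use round-half-away-from-zero. AUC uses
the rank (Mann–Whitney) identity with ties counted ½ and the Hanley–McNeil
standard error (the formula behind "AUC ± SE" is a package choice; none is
named in the source).  The Mann–Whitney test is exact by enumeration for
n₁+n₂ ≤ 12 without ties and otherwise uses the normal approximation with tie
and continuity corrections.  Cross-validation is stratified 5-fold at the
sample level ("leave-p-out with five partitions" is interpreted as 5-fold);
fold assignment depends only on (sample ids, k, seed) — ids are sorted per
class before a seeded shuffle — and an optional patient-level grouping keeps
all samples of a patient in one fold.  Training metrics come from a tree fit
on the full table; CV metrics pool held-out predictions.

## Synthetic cohort generator

No per-sample clinical table is deposited for this panel, so the package
ships a generator whose defaults emulate the study conditions: 494 analysis
samples (goiter 105/50 patients, FTA 101/48, FTC 43/28, HCC 25/11, PTC
121/56, FVPTC 80/32, MTC 19/12), total-RNA concentrations uniform on
1.2–92.6 ng/µl, and a `pre_exclusion` variant with 107/103/44 goiter/FTA/FTC
(the surpluses carrying BRAF V600E against a non-papillary histotype) plus
two anaplastic specimens, so that QC reduces 501 accessioned specimens to
494.

Marker levels are drawn normally on the log2 scale (lognormal linear
quantities).  Lognormality is an assumption of convenience — the source
reports only medians/quartiles in figures — and the default means/SDs are
package constants chosen so each published threshold separates the relevant
groups (goiter/FTA below every malignancy cutoff; HMGA2 high in PTC, FVPTC
and most FTC; miR-146b high in classic PTC and in a 54% papillary-like FVPTC
mixture component; miR-375 very high in MTC; mtDNA/nDNA high in HCC), with
overlaps set so that HMGA2 is the strongest single malignancy marker,
mirroring the reported AUC ordering (HMGA2 > miR-221 > miR-375 > miR-146b).
They are synthetic constants, not estimates from patient data.  Mutations
are Bernoulli draws at the reported group frequencies (RAS: FVPTC 48%, FTC
40%, MTC 21%, HCC 16%), with per-variant splits of the group totals chosen
by us; driver events are mutually exclusive (priority BRAF > RET-PTC1 > RAS
when multiple are drawn), BRAF V600E and RET-PTC1 are restricted to the
papillary family and PAX8-PPARG to FTC.  The single reported
NRAS/RET-PTC1 double-positive case is not emulated by default.  Samples are
assigned to patients round-robin; intra-patient correlation is not modelled.
Cq values above 45 are treated as instrument non-detects and propagate as
missing.

What the generator does **not** emulate: Bethesda category assignment logic,
batch effects, assay noise beyond the configurable `cq_noise_sd`, the 2%
low-RNA samples (off by default, since the 501→494 accounting leaves no room
for them), and real biological outliers such as Hürthle-cell variants of
benign lesions.  Passing tests on synthetic cohorts therefore demonstrate
the correctness and internal consistency of the pipeline, not its clinical
accuracy on real smears.

## Numerical choices and degenerate inputs

* The low-RNA filter is strict ("below 5 ng/µl"): a sample at exactly
  5 ng/µl is retained.
* Entropy uses 0·log 0 = 0; an empty node is an error.
* `best_split` requires at least two distinct values and positive gain;
  otherwise it signals "no split" rather than returning a degenerate
  threshold.
* Leaf majority ties break toward the first class in sorted class order.
* Undefined diagnostic ratios (zero denominator) are `None`.
* Percentages round half away from zero at the printed precision.
* The seeded generator is byte-identical per (config, seed); each histotype
  uses an independent RNG stream so panel-mode and raw-Cq-mode outputs of
  the same seed share the same underlying marker levels (this is what makes
  the normalization round-trip testable to 1e-9).

## Problem sizes used in tests and reproduction

The shipped analyses run at the study's cohort size (494/501 samples).  The
threshold-recovery experiment scales all groups by 27 (so the smallest
histotype, MTC, exceeds 500 samples; 13,338 in total) and checks that the
trainer's root split lands on HMGA2 near log2(0.0918) and that trained and
fixed trees agree on ≥95% of an independently generated cohort.  The
cross-validation optimism property is checked over 50 seeded replicates of
the 494-sample cohort.

## Known limitations

* The printed trees' leaf purities/supports are reproduced as data; the
  trainer cannot be validated against the original fitted trees because the
  underlying clinical table is not public.
* Gain-ratio selection considers only binary splits on continuous
  attributes; categorical attributes (the mutation flags) are not offered to
  the trainer, matching the published feature set.
* The exact Mann–Whitney enumeration is limited to small tie-free samples;
  larger inputs use the asymptotic approximation.
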