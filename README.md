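# thyromir

Molecular classification of thyroid fine-needle aspiration (FNA) samples
from a compact real-time-PCR marker panel.

Cytology cannot reliably separate benign from malignant follicular-pattern
thyroid nodules, which forces diagnostic surgery in many patients.
`thyromir` implements, end to end, a classification pipeline over markers
measurable on a single FNA smear — 13 miRNAs normalized to the geometric
mean of three reference miRNAs by the 2^−ΔCq method, HMGA2 mRNA normalized
to PGK1, the mitochondrial-to-nuclear DNA copy ratio, and seven somatic
driver mutations/fusions — for laboratory scientists and biostatisticians
working on preoperative thyroid diagnostics.

The package provides:

* **normalization** of raw Cq tables into log2 marker levels
  (`log2 level = mean(Cq_ref) − Cq_target`) with sample-level QC: exclusion
  below 5 ng/µl total RNA, and exclusion of specimens carrying BRAF V600E
  against a non-papillary histology (presumed pathology-report errors);
* **mutation rules**: tumor-type specificity checks (BRAF V600E and RET-PTC1
  papillary-only, PAX8-PPARG follicular-carcinoma-only, driver mutual
  exclusivity) and the RAS-based benign/malignant discrimination of
  follicular neoplasms;
* **molecular regrouping** of follicular-pattern tumors: FVPTC split by
  miR-146b into papillary-like vs follicular-like, follicular neoplasms
  split by HMGA2/miR-221/miR-375 into FNMM (markers of malignancy) vs FNNMM,
  yielding five molecular classes (Benign, PTC, MTC, HCC, FNMM);
* **two fixed decision trees** shipped verbatim — a malignancy tree
  (HMGA2 ≥ 0.0918 → malignant; then miR-375 ≥ −12.1213 log2, miR-221 ≥
  0.0105, miR-146b ≥ 1.5362) and a typing tree (miR-375 ≥ 5.2514 → MTC;
  miR-146b ≥ 0.1721 → PTC; mtDNA/nDNA ≥ 5716.3013 → HCC; else FNMM) — plus a
  from-scratch **C4.5-style trainer** (gain-ratio splits, pessimistic
  pruning) behind a statsmodels-style `DecisionTreeModel`/`DecisionTreeResults`
  interface;
* **evaluation**: sensitivity/specificity/PPV/NPV, stratified k-fold
  cross-validation (sample- or patient-level), rank-based ROC AUC with
  Hanley–McNeil standard errors, Mann–Whitney tests, and the
  histology-vs-molecular discordance report;
* a **synthetic cohort generator** reproducing the study conditions
  (494-sample analysis cohort across seven histotypes, or the 501-specimen
  accession cohort whose QC exclusions leave 494), so the whole pipeline is
  testable without clinical data.

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical conventions.

## Worked example

```python
import thyromir as tm

cohort = tm.generate_cohort(tm.default_config(seed=1))       # 494 samples
grouping = tm.molecular_grouping(cohort)                     # 5 molecular classes
data = cohort.assign(
    label=tm.binary_labels(grouping).reindex(cohort["sample_id"]).values)

results = tm.DecisionTreeModel.from_dataframe(data, target="label").fit()
print(results.summary())
cv = results.cross_validate(k=5, seed=1)
print(f"training error {results.total_error:.4f}, CV error {cv.cv_total_error:.4f}")
```

prints

```
Decision-tree classifier
  target:   label
  features: HMGA2, miR-375, miR-221, miR-146b, mtDNA
  n:        494
  total training error: 0.0081

Per-class training metrics (one-vs-rest):
           sensitivity    ppv
benign          1.0000 0.9817
malignant       0.9857 1.0000

Tree:
HMGA2 < -3.549415147
    miR-221 < -6.309110795
        miR-375 < -11.93641966 then Diagnosis = benign (98.2% of 218 examples)
        miR-375 >= -11.93641966 then Diagnosis = malignant (100.0% of 18 examples)
    miR-221 >= -6.309110795 then Diagnosis = malignant (100.0% of 44 examples)
HMGA2 >= -3.549415147 then Diagnosis = malignant (100.0% of 214 examples)

training error 0.0081, CV error 0.0142
```

The trainer rediscovers the structure of the fixed malignancy tree from the
synthetic cohort: the root lands on HMGA2 near the published cutoff
(−3.549 on the log2 scale vs log2(0.0918) = −3.445), miR-375 and miR-221
appear as the secondary splits with thresholds near −12.12 and log2(0.0105)
= −6.57, and cross-validated error exceeds training error, the optimism
pattern expected from a tree grown and evaluated on the same table.

The same steps are available from the shell:

```sh
thyromir simulate --seed 1 --raw -o raw.tsv     # raw Cq cohort
thyromir normalize raw.tsv -o panels.tsv        # 2^-dCq levels
thyromir classify panels.tsv --tree malignancy -o calls.tsv
thyromir report --input panels.tsv -o out/      # full bundle
```

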