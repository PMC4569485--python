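# tcrm — tissue common rejection module scoring for kidney allografts

Acute rejection (AR) of a transplanted kidney is diagnosed histologically,
but the molecular injury it reflects is measurable: an 11-gene *common
rejection module* (BASP1, CD6, CXCL10, CXCL9, INPP5D, ISG20, LCK, NKG7,
PSMB9, RUNX3, TAP1) is over-expressed in rejecting allografts across
organs. `tcrm` implements the tissue qPCR version of that signature for
transplant researchers: from raw threshold-cycle (CT) tables to a per-biopsy
score, an AR classifier, and a predictor of progressive interstitial
fibrosis and tubular atrophy (pIFTA) in histologically normal protocol
biopsies.

The pipeline, stage by stage:

1. **Comparative CT.** For each biopsy and gene, relative expression vs an
   18S endogenous control and a Universal-RNA calibrator sample:
   `FC = 2^−ddCT`, `ddCT = (CT_gene − CT_18S)_biopsy − (CT_gene − CT_18S)_calibrator`.
2. **tCRM score.** The geometric mean of the fold changes,
   `tCRM = 2^(mean log2 FC)`, over the 11-gene panel or the 7-gene pIFTA
   subset (CD6, INPP5D, ISG20, NKG7, PSMB9, RUNX3, TAP1).
3. **Classification.** ROC analysis of the score for AR vs no-AR; the
   Youden-optimal cutpoint is derived on a discovery split and applied
   frozen to a validation split (the published cutoff, score > 2.24, ships
   as a constant); Hanley–McNeil AUC confidence intervals; IRLS logistic
   regression for multivariable correlates.
4. **Lesions and progression.** Pearson/Spearman correlation of the score
   with Banff t/i lesion grades; exhaustive best-subset OLS (all 2047
   subsets, ranked by adjusted R²) of the progressor indicator on log2
   fold changes; paired 6- vs 24-month longitudinal comparisons.

Because the original biopsy-level data were never deposited, the package
includes a calibrated synthetic cohort generator (`tcrm.simulate`) that
reproduces the study design — 146 biopsies from 122 patients: 54 AR + 44
no-AR split into discovery/validation, and 24 paired-biopsy patients (12
pIFTA progressors, 12 non-progressors) — with per-gene fold-change
distributions whose pipeline outputs match the published group means.
See `docs/methods.md` for the model and its calibration.

## Worked example

Run the whole pipeline on a simulated cohort:

```sh
tcrm run-all --out-dir runs/demo        # or: python -m tcrm.cli ...
```

which executes simulate → express → score → classify → pifta and writes
`data/ct_table.csv`, `data/samples.csv`, `expression_matrix.csv`,
`scores.csv`, `classify_report.json`, `pifta_report.json` and a combined
`report_bundle.json`. With the default configuration (seed 20150914) the
classification report contains:

```
AUC 1.000, threshold 2.237 (sensitivity 1.000, specificity 1.000)
validation split at the derived threshold: PPV 1.000, accuracy 1.000
```

The derived cutpoint (2.237) lands essentially on the published decision
threshold of 2.24. The synthetic cohort is calibrated to the published
group *means* only, so it separates AR from no-AR more cleanly than real
biopsies do — single-seed AUCs of 0.97–1.00 — and classification metrics
should be read qualitatively. The pifta report for the same run shows

```
score vs Banff t: Pearson r = 0.742; score vs Banff i: r = 0.768
P vs NP tCRM means: 2.92 vs 1.33 (6 months), 6.85 vs 2.56 (24 months)
```

i.e. the score tracks the extent of tubulitis/interstitial inflammation in
AR biopsies, and six-month protocol biopsies of patients who later develop
pIFTA already score higher than those of patients who do not. The subset
search ranks genes by single-gene adjusted R² (CD6 and its co-planted
genes at the top) and reports the best subset per seed; at n = 24 the
selected set fluctuates around the planted 7 genes from seed to seed,
which is the expected behaviour of best-subset selection at this sample
size (discussed in `docs/methods.md`).

Library use mirrors the CLI:

```python
import tcrm

ct, samples = tcrm.generate(tcrm.default_config())
cohort = tcrm.validate_cohort(ct, samples)
expr = tcrm.build_expression_matrix(cohort)
scores = tcrm.score_cohort(expr)                  # 11-gene tCRM
sub = tcrm.score_cohort(expr, tcrm.PIFTA_GENES)   # 7-gene sub-score
```

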