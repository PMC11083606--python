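# drugsense

Drug-response imputation from tumor transcriptomes, cross-cohort drug
nomination, and constraint-based causal biomarker discovery — packaged as a
tested, fully synthetic-data-verifiable pipeline.

## The problem

Glioblastoma (GBM) drug repurposing screens face two coupled questions:

1. **Which drugs are preferentially effective in GBM?** Direct drug screens
   exist for cancer *cell lines*, not patients. A per-drug ridge regression
   trained on a cell-line panel (expression → dose–response AUC) lets us
   *impute* a drug-sensitivity score for any transcriptome-profiled tumor
   sample; lower imputed AUC = predicted more sensitive. Comparing imputed
   AUC between GBM and non-high-grade-glioma cohorts with a Wilcoxon
   rank-sum test (BH-FDR corrected), ranking by the Hodges–Lehmann location
   shift, and intersecting selections across cohorts (majority of clinical
   datasets plus an avatar model) yields consensus drug nominations.
2. **Which genes *cause* sensitivity to a nominated drug?** Correlation is
   cheap; direction is not. After a univariate Spearman pre-filter, the
   MMPC algorithm discovers the response's parents–children (PC) set via
   Fisher-z conditional-independence tests, and a PC-style orientation pass
   (collider detection + Meek propagation) distinguishes *parental* genes —
   direct causes of response — from downstream markers.

Real inputs are large external cohorts; this package instead ships a
first-class synthetic-data generator that emulates their statistical
structure (linear gene→AUC effects, missing screens, cohort shifts,
platform distortions, causal parent/child/confounded gene roles) with full
ground truth, so every stage is verifiable end to end.

## The statistics, briefly

- Ridge imputation: per drug, `β = (XᵀX + λI)⁻¹Xᵀy` on gene-standardized
  expression and centered AUC over screened lines; λ minimizes the
  closed-form leave-one-out error. Cross-platform samples are first
  harmonized by per-gene rank→quantile mapping onto the training
  distribution. Drugs screened in <40% of lines are removed first.
- Nomination: two-sided Wilcoxon rank-sum (exact by enumeration for small
  tie-free groups, tie-corrected normal approximation otherwise), BH
  step-up FDR across drugs, Hodges–Lehmann estimate
  `HLE = median{x_i − y_j}` (GBM − control; negative = GBM more sensitive);
  selection = significant + GBM-favoring + top fraction by most-negative
  HLE; consensus = selected in ≥3 of 5 clinical cohorts and in the avatar.
- Causal discovery: partial correlation by residual regression, Fisher-z
  statistic `T = √(n−|Z|−3)·atanh(ρ)` (its sign encodes direction: positive
  against AUC ⇒ high expression → resistance), MMPC max–min forward
  selection with backward pruning (conditioning sets ≤ 3), restricted
  PC-stable skeleton + v-structure orientation for parental calls.
- Measured response: trapezoidal AUC of replicate-mean relative ATP over
  the log10 dose axis (nine doses, 0.015–100 nM).

## Worked example

The numbered scripts under `analysis/` run the whole study and write tidy
tables under `results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_impute_drug_response.py
python analysis/03_nominate_drugs.py
python analysis/04_causal_biomarkers.py
python analysis/05_dose_response.py
```

Output of the causal step on the default three-drug study (seed 1):

```
D00: 21 genes past filter, PC=['G0056', 'G0065', 'G0069', 'G0073', 'G0103',
     'G0120', 'G0173'], parental=['G0103', 'G0056', 'G0069']
     (true parents: ['G0056', 'G0069', 'G0103'])
recovery over 20 studies: mean PC F1=1.00, confounded leakage=0%
collider studies (n=2000): parental precision=1.00 over 20 calls
direction labels: 3/3 recovered parents labeled consistently with their
     true effect sign
```

Reading: for drug D00 the Spearman filter kept 21 of 210 genes, MMPC
recovered all six true parent/child genes (plus one cross-drug parent
picked up through cohort structure), the orientation pass called exactly
the three true parents parental, and each recovered parent's
resistance/sensitivity label matched the sign of its true effect on AUC.
The imputation step prints held-out fidelity (mean Spearman 0.91 between
imputed and true AUC on 200 unseen samples), and the nomination step prints
the null false-positive rate (0.2% of 600 inert drugs at q ≤ 0.05, KS
uniformity p = 0.78) and hit-recovery power (recall 1.00, 0 false
nominations across 10 studies).

The same stages are exposed as a CLI (`drugsense simulate | impute |
nominate | biomarker | doseresp | run-all`) and as a single driver,
`drugsense.pipeline.run_pipeline`, which is byte-for-byte deterministic
given config + seed.

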