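# Methods

## Overview

The package implements two discovery procedures over transcriptome data —
cell-line-trained drug-response imputation with cross-cohort consensus
nomination, and constraint-based causal biomarker discovery — together with
a synthetic-data generator that carries full ground truth. This note
documents the models, the defaults and why, what the generator does and
does not emulate, and the numerical choices.

## Synthetic data model

**Cell-line panel.** Gene expression is standard normal per gene
(log-scale expression after normalization is approximately Gaussian; the
generator works directly on that scale). Each drug has disjoint sets of
role genes:

- *parents* (default 3, weight magnitude `effect_size` = 1, random sign):
  the drug's raw response is `r = Σ w_g · x_g + ε`, `ε ~ N(0, noise_sd²)`
  with `noise_sd` = 1 — a moderate regime in which the three parents
  explain 75% of response variance;
- *children* (default 3): generated as a linear read-out of the
  standardized response realization plus noise, rescaled to unit variance.
  Children load on the realization `r` itself, not on the noise-free
  linear predictor: the predictor is a deterministic function of the
  parents, so a child driven by it would be d-separated from the response
  given the parents and no sound discovery algorithm could keep it in the
  PC set. Loading on `r` makes the response→child edge genuine and
  preserves the parent/child asymmetry the orientation stage relies on;
- *confounded bystanders* (default 4): unit-variance mixtures of one
  parent and noise — correlated with response marginally, conditionally
  independent of it given that parent. They are the negative controls for
  the conditional-independence machinery;
- the remaining genes are independent bystanders (an optional
  equicorrelated-block knob exists and defaults to off).

Screen AUC is the response affinely min–max rescaled per drug into the
10–20 band conventional for large screening portals (rank-preserving, so
all downstream rank statistics are unaffected); screens are masked
completely at random at rate `missing_fraction` = 0.2 (no mechanism is
asserted for real missingness). The truth object records roles, weights,
and the affine parameters, so noise-free "true" AUCs are computable for
any sample.

**Patient cohorts.** Each cohort draws fresh samples; GBM samples have each
truly-sensitive drug's parent genes mean-shifted by
`−sensitivity_shift · sign(w)` (default 1.0), which lowers the latent
response, hence the AUC: GBM imputes as more sensitive. Control (clinical)
and NPC (avatar) samples are unshifted. Children and confounded genes are
regenerated from the cohort's own responses/parents. Cohorts expose both
the noise-free true AUC and the observed response realization per sample.

**Platform effect.** The monotone distortion applies a per-gene random
strictly increasing cubic `a + b·x + c·x³` (`b, c > 0`) — a stand-in for
cross-platform (microarray vs RNA-seq) scale distortions. It preserves
per-gene rank order, which is exactly the information the harmonization
step keeps.

**Dose–response plates.** Nine doses log-spaced over 0.015–100 nM, six
technical replicates per dose. Relative ATP follows a four-parameter
logistic in log-dose (top 100%, per-sample EC50 drawn log-uniformly from
1–30 nM, maximal effect ~80% for GBM and ~15% for NPC with ±15%
multiplicative jitter, Hill 1.2) plus replicate noise (sd 4% ATP). The
noise-free trapezoidal AUC of each underlying curve is recorded as truth.

**What the generator does not emulate:** probe/batch artifacts beyond the
monotone map, tumor purity, subtype structure, gene–gene regulatory
networks among bystanders, informative missingness, and non-linear
gene→response effects. Recovery results on this generator therefore
certify the *statistical machinery* under its stated assumptions (linear
Gaussian effects, faithfulness), not performance on real cohorts.

## Imputation

Per drug, ridge regression of AUC on gene-standardized expression
(training mean/SD, stored for prediction) with centered response, fitted
only on lines actually screened for that drug; intercept = training mean.
The penalty is chosen by minimizing the closed-form leave-one-out error
`Σ((y_i − ŷ_i)/(1 − h_ii))²` over a 25-point log grid from 1e−4 to 1e4
(a fixed-λ mode exists for verification). The solution is computed from
the SVD of the standardized design, which makes the LOO identity and the
shrinkage path cheap and exact. Zero-variance genes are dropped with a
warning; drugs trained on fewer than 20 lines are flagged. Drugs screened
in <40% of lines are removed first (strict inequality: exactly 40% is
retained). All shared genes are used — no variable pre-selection.

**Harmonization.** Cross-platform test samples are mapped gene-by-gene
onto the training distribution: test values are replaced by the empirical
train quantiles at the test midrank positions. Only ranks survive, so any
per-gene monotone distortion is removed exactly, the map is idempotent,
and downstream Spearman/rank-sum statistics are invariant to the original
platform scale. This is a deliberately simple rank-based integration
procedure; it treats genes independently and assumes the train
distribution is a valid reference for the test population.

## Nomination

Two-sided Wilcoxon rank-sum per drug: full enumeration of group
assignments (valid under ties, using midranks) when both groups have ≤10
observations, pooled ≤20 and the data are tie-free in auto mode;
otherwise the tie-corrected normal approximation with continuity
correction. BH step-up FDR across the drugs of one dataset (the family is
per dataset-comparison). Effect size is the Hodges–Lehmann estimate of
GBM − control (negative ⇒ GBM more sensitive). Selection in a dataset
requires q ≤ 0.05, HLE < 0, and membership in the most-negative
`percentile` fraction (default 0.5, ceil-rounded, boundary ties included —
a lone significant drug is selected); a `direction="both"` mode ranks all
significant drugs by |HLE| instead. Consensus nominates drugs selected in
≥3 clinical datasets and (by default) the avatar dataset, and separately
reports drugs passing the clinical majority but failing the avatar gate.

Two properties of the rule worth knowing:

- *The percentile gate caps recall.* Each dataset selects at most
  `ceil(n_significant/2)` drugs at the default 0.5. When exactly the true
  hits are significant — the clean synthetic regime — recall cannot exceed
  ~50%. The power study therefore evaluates the chain with the gate open
  (percentile 1.0) and reports the gated variant alongside; on real data,
  where significant drugs outnumber real effects, the gate behaves as the
  conservatism dial it is meant to be.
- *Imputed null scores are projections.* A null drug's model weights are
  noise, and the rank-sum test is scale-invariant, so a cohort-level shift
  in a few genes can leak a small but dataset-consistent group difference
  into a null drug's imputed score (observed at ~1 drug per 100 per study
  at 887 training lines). The false-positive studies quantify this; the
  percentile gate and larger training panels both suppress it.

## Causal biomarker discovery

**Pre-filter.** Per-gene Spearman correlation against the drug's response,
BH-adjusted; retained iff q < 0.05 and |r| ≥ `r_min`. The conventional
cutoff 0.60 is the per-call default and is kept for user-facing filtering.
The synthetic recovery studies filter at `r_min` = 0.30: with `k` parents
sharing the response variance the marginal parent–response correlation is
bounded by `1/√k` (0.577 at k = 3), so 0.60 would exclude every parent of
a three-parent drug *by construction*; 0.30 is still ≈6.7 null standard
errors at n = 500 and keeps the candidate set in the tens.

**CI testing.** Partial correlation by the residual method (OLS of both
variables on the conditioning set, Pearson correlation of residuals);
inside the search loops it is computed equivalently from the inverse of
the correlation submatrix, with a cache. The Fisher-z statistic
`T = √(n−k−3)·atanh(ρ)` is signed; |ρ| = 1 is reported as ±∞ with p = 0.

**MMPC.** Forward: candidates (processed in descending-|SCC| order, ties
by gene ID, to neutralize variable-order dependence) are added by the
max–min-association heuristic — the candidate whose *weakest* association
over all conditioning subsets of the current PC set (≤ `max_k` = 3) is
strongest — while that weakest association stays significant at
α = 0.05; candidates whose minimum association becomes non-significant
are permanently discarded. Backward: a member is removed if any subset of
the remaining members separates it from the response. Each surviving gene
carries the signed statistic of its weakest surviving test (the
elimination semantics: the evidence that almost removed it). `max_k` = 3
bounds both runtime and the conditioning dimension; α applies to CI tests
(the FDR threshold governs only the pre-filter).

**Orientation.** The local context is the response, its PC genes, and each
PC gene's own PC set (MMPC re-run per gene with the response included as a
candidate). Over this context: PC-stable skeleton (neighbor sets
snapshotted per depth, so edge-removal order cannot matter), v-structure
orientation (x → z ← y when x, y are non-adjacent and z is outside their
separating set), then Meek rules R1–R3 to propagate orientations without
creating cycles or new colliders. Parental genes are PC genes with an edge
oriented into the response. Undetermined orientations are reported as
undirected, never forced — a lone PC gene with no collider evidence stays
undirected.

**Report.** One row per retained gene: Spearman r/q, PC membership, signed
statistic, parental call, and a direction label — positive statistic
against AUC ⇒ "high expression → resistance" (higher AUC = less
sensitive), negative ⇒ sensitivity.

**Response choice for recovery scoring.** The recovery studies test
against the generator's *observed* response rather than the imputed score:
ridge spreads weight across correlated predictors, so the imputed score is
itself a direct linear function of child and confounded genes and the
generative conditional independencies do not hold for it. The
imputed-response configuration — what a user runs on real cohorts — is
exercised end to end in the analysis scripts and pipeline; on the default
study it recovers parents with more noise (occasional cross-drug PC
members), which is the expected cost of conditioning on an estimated
response.

## Measured response

Trapezoidal AUC of the replicate-mean relative-ATP curve, by default over
the log10 dose axis: the dose grid spans nearly four decades, and a
linear-dose trapezoid would be dominated entirely by the top dose. The
replicate aggregation is the mean of the six technical replicates per
dose. No sigmoid is fitted for AUC — the empirical curve is integrated
directly; 4PL fitting is used only inside the generator. Group comparison
delegates to the same Wilcoxon/Hodges–Lehmann machinery as nomination.

## Study conditions used by the evaluation

All in `drugsense.studies`, shared by the analysis scripts, the acceptance
tests and `scripts/acceptance.py`:

| study | conditions |
|---|---|
| null calibration | 12 independent studies × 50 inert drugs (effects and shift 0), 500-line panel, 100+100 cohort; pooled because each study's null p-values share a cohort-level tilt (they are projections of one realized cohort), making single-study KS anti-conservative even under exact marginal calibration (pooled check: KS p = 0.50 on 1200 p-values) |
| nomination power | 10 studies; 100 drugs (2 parents each), 20 true hits, shift 1.0, 5 clinical + 1 avatar cohorts at 80/group; scored on observed response with percentile 1.0 (see above) |
| imputation fidelity | default panel (500 lines, 210 genes, noise 1.0, 20% missing), 200 held-out cohort samples |
| causal recovery | 20 studies; 3 parents / 3 children / 4 confounded / 200 bystanders, 500 discovery samples, no group shift, filter r_min 0.30 |
| collider orientation | 10 studies; 2 parents / 2 children / 2 confounded, 2000 samples |
| directionality | single study of the causal config; labels of recovered parents vs true weight signs |

Sizes were chosen to keep each study in seconds on one CPU while leaving
the measured quantities far from their pass/fail boundaries; the full
evaluation runs in ~20 s.

## Numerical and degenerate-input choices

- Determinism: every generator draws from named substreams of the single
  study seed; identical config + seed gives byte-identical output tables.
- Degenerate screens: a constant-response drug rescales to AUC 15
  everywhere (slope 0); constant genes are dropped from ridge fits and
  reported NaN by correlation routines, with warnings.
- Harmonization with a single test sample maps to the train median; ties
  use midranks and linear quantile interpolation.
- Exact Wilcoxon enumeration is capped at pooled n = 20 (C(20,10) splits).
- MMPC tie-breaks (equal |T|) fall back to the SCC processing order;
  skeleton search iterates variables in sorted order.
- The ridge LOO denominator `1 − h_ii` is floored at 1e−10; hat values of
  1 (interpolating fits) therefore select larger penalties automatically.

## Known limitations

- All effects are linear and Gaussian; MMPC's Fisher-z tests would need
  replacement (e.g. rank-based CI tests) for heavy-tailed or non-linear
  real data.
- The harmonization treats genes independently; co-expression distortions
  that permute ranks differently across correlated genes are not corrected.
- The imputed-score leakage described under Nomination means null drugs
  are not perfectly null once imputation enters; consensus plus the
  percentile gate mitigate but do not eliminate this on real data.
- Parental calls require collider evidence; a drug whose response has a
  single parent gene and no other context stays undirected by design.
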