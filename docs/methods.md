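# Methods

This note documents the statistical models, the numerical choices and the
synthetic-data machinery behind `clrbalance`, and what the test suite does
and does not establish about real data.

## Compositional treatment

Sequencing counts are treated as compositions: per sample only the
relative abundances are informative. All taxon-level analyses follow the
chain *aggregate to rank → impute zeros → close → clr*.

**Rank aggregation.** Lineage strings are parsed with two 16S
post-processing conventions: a slash joins the members of an unresolved
ambiguity set (`Blautia/Dorea`), which compares as an unordered set during
aggregation, and a trailing `_u` marks a taxon unclassified at that rank,
inheriting the parent label (`Lactobacillus_u`; markers stack one per
unresolved rank). Aggregation sums counts over taxa sharing the label path
down to the target rank and preserves per-sample totals exactly.

**Zero replacement.** Zeros are replaced by a geometric
Bayesian-multiplicative (GBM) estimate: in sample *i* with depth
*n<sub>i</sub>* and prior strength *s<sub>i</sub> = √n<sub>i</sub>*, a zero
part *j* receives the posterior-expected proportion
*t<sub>j</sub>·s<sub>i</sub>/(n<sub>i</sub>+s<sub>i</sub>)*, where
*t<sub>j</sub>* is the normalized geometric mean of part *j*'s nonzero
observed proportions across samples; the observed parts are
multiplicatively rescaled so the sample re-closes to 1. A part never
observed in any sample has an undefined geometric-mean prior and falls
back to a uniform weight 1/D before normalization; the pipeline drops
all-zero taxa before imputation, so the fallback only matters for
single-sample or deliberately degenerate inputs. An all-zero sample is an
error naming the sample.

**clr and Aitchison geometry.** `clr(x)_i = ln(x_i/g(x))`; rows sum to
zero. Beta diversity is the Euclidean distance between clr rows. PCA is
run on taxon-centred clr values, which makes it identical to principal
coordinates of the Aitchison distance.

**Diversity.** Chao1 is `S_obs + F1²/(2·F2)` with the bias-corrected
fallback `S_obs + F1(F1−1)/(2(F2+1))` only when `F2 = 0` (avoiding the
division by zero with minimal deviation from the classic estimator),
computed after rarefaction without replacement (multivariate
hypergeometric draw) to a fixed depth, default 3000 reads. Samples below
the depth are excluded from diversity analyses and listed in the run log
rather than raising.

## Association models

Per-feature models run on clr taxon values (per rank) and on
log2-transformed metabolite concentrations (pseudocount 0.001 µM, so
below-LOD values stored as 0 map to log2(0.001) ≈ −9.97).

* **Cross-sectional (health status).** One sample per subject (the first
  time point); OLS of the feature on the binary group indicator. The
  coefficient is the group contrast and the slope t-test is algebraically
  the equal-variance two-sample t-test; the implementation is the
  vectorized closed form and is tested against `scipy.stats.ttest_ind`.
* **Longitudinal.** All time points, linear mixed model
  `feature ~ outcome + (1 | subject)` fitted by REML (statsmodels MixedLM)
  with a Wald z test on the fixed slope. Non-converging fits fall back to
  OLS and are flagged; with one observation per subject the GLS slope
  equals OLS regardless of the variance split, which the tests verify.
* **ANCOVA on changes.** For subjects with ≥2 time points, Δ = last −
  first is modeled on the dynamics group with the first-time-point value
  as covariate; the group-effect p is reported. The dynamics factor is the
  modeled group, an interpretation documented here because the verbal
  description of this analysis admits more than one reading.
* **Multiplicity.** Benjamini–Hochberg step-up, applied separately within
  each adjustment family = (metadata group × data type). Taxonomic ranks
  are adjusted *together* within a family. The step-up is implemented
  directly (sort, p·m/i, reverse running minimum): library variants that
  divide by i/m differ in the final ulp and the package's contract is the
  textbook definition. Zero-variance features get p = 1 and a flag instead
  of being dropped, keeping family sizes stable across runs.
* **Diagnosis.** One-vs-rest indicators per category, skipping categories
  with fewer than 5 patients.

## Balance selection

A balance on disjoint taxon sets (sizes r, s) is the ilr log-contrast
`sqrt(rs/(r+s))·(mean ln x[num] − mean ln x[den])`. The selection
criterion is the Mann–Whitney AUC of the balance values against a binary
outcome, or the adjusted R² of a simple regression for a continuous one —
no covariates enter the selection.

**Greedy growth.** Step 1 scores every ordered taxon pair and keeps the
best. Each later step scores the addition of every unused taxon to either
side and keeps the best strictly improving addition, stopping at no
improvement or at `max_size` (default 10). Ties break to the
lexicographically smallest taxon ID (numerator side preferred), making the
search deterministic. Pair and addition scoring are vectorized (rank-based
AUC / correlation-based R² over candidate score matrices).

**Cross-validation.** Stratified (binary) or plain 5-fold CV repeated 10
times → 50 fold-fits, each rerunning the greedy search on the training
fold. The balance size is chosen over the growth traces by the
one-standard-error rule on the mean held-out criterion per size — the
usual parsimony rule; a plain argmax chases noise-level CV gains and
overgrows the balance. Each fit's selected balance is its trace truncated
to the chosen size; *reproducibility* of a taxon is the percentage of
fits containing it on a given side. The final balance is the full-data
trace truncated to the chosen size. Everything is driven by one seed; fold
assignments that leave a class absent from any fold are resampled up to 10
times before erroring.

**Reliability.** A taxon is *reliable* when its reproducibility exceeds
50% and the final model R² exceeds 0.2. For continuous outcomes the R² is
the adjusted R² of the outcome on the balance value; for binary outcomes
it is the McFadden pseudo-R² of a logistic fit (taken as 1 under perfect
separation, where the likelihood is unbounded). Both are computed from
**pooled out-of-fold balance values**, not in-sample: a balance selected
on the same data it is scored on carries selection-induced optimism —
measured on null cohorts, the in-sample pseudo-R² of the selected balance
exceeded 0.2 in more than half of the runs, which would defeat the
filter's purpose, while the out-of-fold value sits near 0 under the null
and stays high under planted signal.

A caveat worth stating: with 5-fold CV the training folds share 80% of
their samples, so under a pure-noise outcome the best noise pair tends to
recur across fold-fits and single-taxon reproducibilities above 50% are
common. Reproducibility alone is therefore not a null filter; only the
conjunction with the out-of-fold R² gate is.

**Rank choice.** The rank used for balance selection is the one whose
per-feature linear-model results contain the globally smallest FDR, ties
broken toward the finer rank.

**Time points.** Health-status selection uses the first time point per
patient; dynamics and metabolite-association selection use the last.

## Synthetic cohorts

The generator emulates the repeated-measures, two-cohort structure the
models assume. Defaults: 44 patients — 18 with one sample, 16 with two, 7
with three and 3 with four (83 samples; the three-or-more split is chosen
to land on that total) — plus 20 single-sample healthy controls; 150 taxa
nested 3 species/genus, 3 genera/family, 3 families/order with periodic
slash-ambiguity and `_u` names; sequencing depth uniform on
10,000–50,000; clinical dynamics split ~15:29 positive:negative with
NIHSS drifting down (positive) or up (negative) across weekly time
points; diagnosis categories in proportions 16:13:12:3.

Log abundances are multivariate normal: per-taxon means with SD 1.5, a
per-patient intercept vector (SD 0.4) shared across that patient's time
points, and per-sample noise (SD 0.7); counts are multinomial at the
sampled depth (logistic-normal/multinomial — the minimal generative model
consistent with clr-based analysis). Planted effects:

* **Balance** — the patient group's log abundances shift along the unit
  clr contrast of the planted balance, moving the balance value by exactly
  the configured amount (default 2.0 on the log scale).
* **Slope** — one taxon's log abundance follows
  `slope·(outcome − mean) + b_patient + noise` (defaults 0.3, SD 1.0, SD
  0.5), the random-intercept structure the mixed models assume.
* **Metabolite coupling** — concentration = baseline +
  coefficient·balance value + patient intercept + noise, censored at the
  LOD (default 0.1 µM) after noise, as detection acts on realized
  concentrations. Baselines sit near typical serum panel medians (e.g. SA
  6.3 µM, p-HPhLA 0.8 µM).

The truth object records planted memberships, shifts, slopes and
couplings and is serialized beside the data; `score_recovery` computes
membership precision/recall, planted-taxon reproducibility and slope
bias against it.

What the generator does **not** emulate: phylogenetic correlation between
taxa (taxa are independent given the planted effects), overdispersion
beyond multinomial sampling, batch effects, or informative missingness of
time points. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the assumed model, not performance on
real sequencing data.

## Problem sizes and numerical choices

The simulation suite uses: 50 null cohorts (40 taxa, 20+20 samples) for
FDR control; 20 replicates of a planted two-taxon balance (log-ratio
shift 2.0, 30+30 samples, 40 taxa) plus 20 null replicates for recovery;
100 random-intercept simulations (40 subjects × 3 time points) for
mixed-model recovery; and one full study-shaped cohort (103 samples, 150
taxa, 11 metabolites, shift 3.0) run twice end-to-end for bit-identical
outputs. The strong end-to-end shift is deliberate: at much larger shifts
a single taxon separates the groups alone, the pair criterion saturates
at AUC 1.0 and the denominator partner becomes tie-arbitrary, while at
small shifts recovery is statistical rather than exact.

Floating-point contracts: clr row sums |Σ| < 1e-9; imputation closure
within 1e-9; greedy improvement threshold 1e-12 (criterion ties resolve
by taxon ID); BH is bitwise the step-up definition. All stochastic stages
derive integer substream seeds (< 2³¹) from the single pipeline seed, so
repeated runs are byte-identical; the run manifest records the seed,
family sizes and diversity exclusions.

## Known limitations

* The balance search is greedy: it finds a good balance, not the global
  optimum, and only one balance per outcome (no forests of balances).
* Mixed models are random-intercept only; no serial correlation within
  patients.
* Reliability thresholds (50%, 0.2) are the field's convention, applied
  as configurable defaults; they are not calibrated error rates.
* BIOM input requires the optional `biom-format` package; the native
  dialect is TSV.
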