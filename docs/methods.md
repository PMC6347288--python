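# Methods

This note documents the models and procedures implemented in `mspair`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data generator does and does not emulate.

## Preprocessing

Input is a processed profiling matrix (peaks detected, aligned, quantified;
some signals identified as knowns). The pipeline applies, in order:
optional natural-log transform; per-signal outlier masking (|x − median| >
k·1.4826·MAD set to missing, default k = 5, signals with MAD = 0 skipped);
missingness filtering (signals with more than `signal_missing_max` missing
dropped first, then samples, computed on the retained signals — default
0.5, the order is a package choice since only the thresholds are
methodologically fixed); chained missing-value imputation; optional
covariate adjustment (OLS residuals on intercept + covariates; collinear
sets are an error); and a rank-based inverse normal transform per signal.

The imputer is a deterministic chained regressor, not multiple imputation:
columns are initialized at their means, and for a fixed number of rounds
(default 5) each incomplete signal's missing entries are re-predicted by
OLS on its `impute_predictors_max` (default 20) most-correlated other
signals. Observed entries are never altered. Determinism was preferred
over posterior draws because every downstream statistic consumes a single
completed matrix and byte-identical reruns make the whole pipeline
replayable; the cost is that imputation uncertainty is not propagated.

The inverse normal transform uses the Blom offset, z = Φ⁻¹((r − 3/8)/(n +
1/4)) with average ranks for ties. The offset choice is conventional and
immaterial downstream (all consumers are rank- or correlation-based).
Phenotype z-scores residualize the raw phenotype on covariates first, then
apply the same transform; per-signal association uses simple OLS with a
Bonferroni threshold of 0.05 / #signals.

## Matching

Two signals' m/z values *agree* when (mz₁ − mz₂) is within `tolerance`
(default 0.005 Da) of some allowed shift difference *d*. In the
`no_adduct` setting only the primary ion of each mode contributes
([M+H]⁺, [M−H]⁻), so *d* is a single value (0 for same-mode pairs,
2·1.00728 for positive-negative pairs). In the `adduct` setting all adduct
pairs contribute; the default positive-mode table is M⁺ (−0.000549 Da,
electron loss), [M+H]⁺ (+1.007276), [M+NH₄]⁺ (+18.033823), [M+Na]⁺
(+22.989218), negative mode [M−H]⁻ (−1.007276), all derived from standard
atomic masses and user-extensible. `combined` uses the no-adduct candidate
list per query signal and falls back to the adduct list only when it is
empty. Partitioning restricts candidates to the same profiling method
(configurable alias map, default LIPID = C8-pos) or allows cross-method
matching.

Imputation-based correlation: for each signal of dataset A, an OLS model
on the shared known metabolites of A predicts that signal in dataset B's
samples (minimum-norm solution when rank-deficient). A shared-known
signal's own model always excludes itself from the predictors, so no
metabolite is ever predicted from its own measurements. Correlation can be
computed over the query dataset's samples (observed vs imputed), the
candidate dataset's samples, or both concatenated (observed where native,
imputed otherwise); the setting labels are interpreted relative to the
query dataset so that the reciprocal direction is well-defined.

Candidates are ranked by signed Pearson r: a true match is imputed from
the same predictors as its partner and is therefore positively correlated,
so |r| or r² ranking would only promote sign-flipped artifacts. Ties are
broken by smaller m/z residual, then lexicographic signal id. The optional
correlation cutoff keeps only matches with r strictly above the cutoff.
Match types: `multiple` (per query signal, the best-correlated candidate),
`unique` (additionally, per candidate only the best query), `reciprocal`
(pairs present in both directed unique maps; an injective partial
bijection by construction). The RT baseline replaces the correlation
ranking with |observed − predicted RT| where the RT shift between datasets
is a per-method linear fit on shared knowns.

Calibration treats each shared known in turn as unmatched and re-matches
it (leave-one-out models throughout), reporting per setting: the number
matched, the fraction matched to themselves (`correct_fraction`), the
fraction matched to a candidate whose observed-data squared correlation
with the true known (within the candidate's dataset) exceeds 0.8
(`rsq08_fraction`), and the incorrect-but-highly-correlated remainder.

## Metabolic components and reconstitution

Metabolic components are the eigenvectors of the signals x signals
Spearman correlation matrix of a complete dataset, ordered by eigenvalue;
variance explained is eigenvalue / trace. Raw eigenvector loadings are the
signal-MC scores (eigenvalue-scaled loadings are available behind a flag;
scaling only reweights MCs and the default keeps each selected MC equally
informative for the rank-based scoring that follows).

Curated pathways are consolidated into metabolite sets: members are
intersected with the dataset's knowns, pathways with identical profiled
member sets merge into one set carrying all labels, and sets below
`min_size` (2, 5 or 10) are dropped.

For each (set, MC) pair a two-tailed Wilcoxon rank-sum test compares the
MC loadings of in-set vs out-of-set knowns. The signed normal deviate
(positive when in-set loadings are larger; tie-corrected variance, 0.5
continuity correction) fills a set x MC z matrix; for pooled sizes of 20
or fewer observations the p-value is computed by exact enumeration instead
of the normal approximation, so small-sample uses are exact and large ones
fast. A signal's membership score in a set is the Spearman correlation
between its loading vector and the set's z vector across the selected MCs.
For a known curated in the set, the z row is recomputed without that
metabolite before scoring it (leave-one-out), which changes no other
cell. MC selection options: top-N by variance explained (50, 100, all) or
MCs enriched for at least one set at permutation FDR 0.01/0.05, where the
FDR at a p-value threshold is (mean null count ≤ p over 20 known-row
permutations) / (observed count ≤ p). At least 3 MCs are required.

Scores convert to two-sided p-values via t = r·sqrt((k−2)/(1−r²)) on k−2
degrees of freedom (k = number of selected MCs; |r| = 1 gives p = 0).
Quality is measured two ways: the AUC of classifying (known, set)
membership pairs by −p, with a label-permuted null for comparison, and a
per-set *label confidence score* — the rank-sum p testing whether the
absolute scores of the set's curated members exceed those of the other
knowns. Sets with label confidence p < 0.05 form the "filtered"
annotation.

## Enrichment statistics

Given a positive and a negative signal list, the nominal enrichment p per
set is a two-tailed rank-sum test on absolute membership scores (absolute,
because a strong negative score is evidence of relatedness under the
signed Spearman construction). The permutation layer shuffles the
per-signal trait statistic across signals, takes the top-N re-ranked
signals as a null positive list (N = observed positive count) and
recomputes the nominal p; the permutation p is the inclusive proportion of
1000 null p's at or below the observed one (a `plus_one` flag gives the
conservative (k+1)/(n+1) variant). Because the trait enters only through
the ranking, the permutation p is invariant to monotone transforms of the
association statistic. The FDR layer scores 20 further null lists against
the same 1000 first-round nulls to obtain null permutation p's; FDR(P) =
(mean null count ≤ P per list) / (observed count ≤ P), clamped to [0, 1].
Monotonization uses a running maximum from the smallest permutation p
upward: the constraint is only that a smaller p never carries a larger
FDR, and of the two scans satisfying it, the upward running maximum is the
conservative one (estimates are only ever raised) and keeps the FDR near 1
under a fully null trait, whereas a downward running minimum provably
drags small-p FDRs below their expectation by taking the minimum of many
noisy ratios.

Overrepresentation analysis for knowns-only inputs builds the 2x2 table of
set membership vs trait association per set and computes the one-sided
hypergeometric upper-tail p, with the identical permutation-p and FDR
layers (null positive lists are same-size draws from the known universe).
The overlap-significance helper exposes the same upper-tail p for
comparing two enriched-set lists.

## Genetic validation

Fixed-effect inverse-variance meta-analysis: w = 1/se², combined beta =
Σwb/Σw, se = 1/√Σw, two-sided normal p; the direction-ignoring variant
takes |b| first and is used only to *select* each matched pair's best
variant (ties to the lexicographically smaller variant id), so that
selection is blind to sign agreement. A pair is directionally consistent
when its original betas share a sign (zero counts as inconsistent —
conservative). Consistency fractions are tabulated at descending meta-p
thresholds; significance against the 50% chance level is the two-sided
exact binomial (tail-doubling, which at p₀ = 0.5 equals the
minimum-likelihood convention). Empirical p's re-run the whole pipeline on
shuffles of the dataset-2 partners (p = proportion of null fractions ≥
observed). The true-positive fraction is (c − 0.5)/(s − 0.5) clamped to
[0, 1], where c is the matched-pair consistency and s the shared-known
consistency: an unclamped version would exceed 1 whenever matches
outperform the shared-known ceiling, which is sampling noise, not signal.

Locus-level pathway validation filters variants to those associated with
at least 5 study signals at p < 1e-5, coding (missense/nonsense), in genes
linked to at least one reconstituted pathway, one variant (best p) per
gene. Study signals map to the annotation reference through a match
table; per locus, the mapped signals form the positive list of a rank-sum
enrichment, and the locus validates at a threshold when an enriched set
carries a pathway label linked to the gene. Null iterations redraw each
locus's positive list uniformly from the reference signals (emulating
association results under permuted genotypes); the empirical p is the
proportion of null locus counts at or above the observed count.

## Synthetic data

The generator emulates the statistical regime the methods assume, not
LC-MS physics. Latent metabolites follow a factor model with module
structure: each metabolite loads √0.8 of its common variance on one
primary factor plus a dense random background, communality 0.75, so
within-module observed correlations are ~0.4–0.6 — the regime in which
pathway modules and imputation both work on real profiling data.
Measurement noise (default sd 0.25 per signal against unit-variance
latents) and the communality were set so that the *observed*
correlation-of-correlations similarity between cohorts can reach ~0.62,
the high end of what real profiling dataset pairs achieve; similarity targets
up to that ceiling are honored by bisection on the mixing weight between a
shared and an independent loading matrix, measured on the observed known
signals (noise included). The ceiling itself fluctuates with the seed; a
target within 0.02 of it (the calibration's own accuracy scale) uses the
closest attainable mixing, while targets further beyond the ceiling raise
an error after the 50 bisection attempts. A target of exactly 1.0 means
"identical loadings" (sampling noise keeps the realized value below 1).

Signal layout: neutral masses are uniform on 80–900 Da with ≥ 0.02 Da
spacing; every latent emits an [M+H]⁺ signal (named and shared for the
first `n_known` metabolites), extra unknown signals cycle through the
remaining adduct profile, and a configurable fraction of knowns (default
0.5) receives an m/z-colliding decoy signal from a different latent within
±0.004 Da — collisions are the controlled source of matching difficulty.
Default conditions are 300 samples per cohort, 260 latent metabolites, 200
shared knowns and similarity 0.6, the guideline regime for which the
matching method is designed. Retention times follow a per-cohort linear
shift with small noise. Association statistics draw one effect per
(variant, metabolite), shared across cohorts with a configurable
probability, add sampling noise with se = 1/√n, and propagate to every
signal of the metabolite.

What the generator does not emulate: batch effects and platform drift,
isotope envelopes, multiply charged ions, chromatographic RT nonlinearity,
heteroskedastic or missing-not-at-random measurement error, and
correlation between matching difficulty and biological module structure
(decoys are drawn independently of the true signal's module, so matching
recovery on synthetic data is near its ceiling and should be read as a
correctness check of the pipeline under the stated conditions, not a
forecast of recovery rates on real cohorts).

## Problem sizes and determinism

Every generator and permutation consumes an explicit integer seed; reruns
are byte-identical. The test and acceptance runs use 5 simulated cohort
pairs at the guideline regime for matching calibration, 100 null-trait
replicates (1000 permutations, 20 null lists each) over a 100-set
annotation matrix for enrichment calibration, reconstitution at 50/150/300
knowns for the known-count scaling check, and ~2000 matched pairs for the
chance-consistency check — sizes at which the binomial/permutation noise
is small against the tolerances being checked.
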