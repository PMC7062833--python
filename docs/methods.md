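# Methods

This note records the models, estimators and numerical conventions the
package implements, the design choices made where several reasonable
options existed, and what the synthetic-data experiments do and do not
establish.

## Cohort structure and inputs

A cohort is three tables: an immune matrix (one row per blood sample;
subject id, postnatal age in days, ~186 parameters that are subset
frequencies in %, MFI, or absolute counts), a family-level taxa table
(relative abundances summing to 1 per stool sample), and an adult
reference (same immune parameters, one row per donor). Parameter kind
rides on the column name (`name|kind`; bare names are frequencies) so
MFI and % can be transformed differently downstream. Missing cells stay
missing at I/O time — imputation is an ordination concern, not a
parsing concern. Ages are decimal days throughout; "days preterm" is
280 − gestational age at birth in days. Subjects present only in the
taxa table are retained: stool passage is unpredictable and blood and
stool schedules need not match.

## Adult deviation and longitudinal slopes

For each parameter the first blood sample per subject is compared with
the adult donors: log2 fold change is the median over subjects of
log2((first + ε)/(adult median + ε)), with ε defaulting to half the
smallest positive observed value — a scale-aware pseudocount that keeps
ratios finite when zeros occur. Group testing uses the two-sided
Wilcoxon rank-sum test (exact enumeration at small n via scipy) with
Benjamini–Hochberg correction across parameters.

Group-level change with age uses a linear mixed model with a random
intercept and slope per subject, fitted by REML (statsmodels MixedLM).
Each sample contributes one row, so babies with more samples carry
proportionally more weight — this realises samples-per-baby weighting
without separate case weights. On degenerate data (zero residual
variance) the fit falls back to pooled OLS, which is the exact
mixed-model limit there; the same limit anchors the contract tests. A
cheaper per-subject alternative (OLS slope per baby, averaged with
weights proportional to sample counts) is emitted alongside the mixed
fits, since per-baby regression coefficients and mixed-model slopes
answer slightly different questions; the quadrant map uses the mixed
fit. MFI parameters are log10-transformed before slope fitting (their
change is multiplicative); frequencies are fitted on the raw % scale.
Wald 95% interval coverage for the fixed slope is verified at ~95% over
200 simulated cohorts.

Quadrant labels come solely from the signs of (log2FC, slope); exact
zeros classify as start_low / decreasing — an arbitrary but documented
tie rule. Slope significance is starred at 0.05 / 0.01 / 0.001.

## Profile geometry

All parameters are z-scored (mean/SD over retained samples) after
median imputation of missing cells, and projected by PCA on the
correlation structure — parameters mix % and MFI scales, so covariance
PCA on raw values would be dominated by high-MFI channels. Zero-variance
parameters are dropped with a warning. The standardisation statistics
are carried in the result object so a non-standardised variant can be
compared. Each baby's developmental movement is the Euclidean distance
in (PC1, PC2) between the earliest sample at age ≤ 7 days and the
sample closest to day 37 within days 28–49 (the windows generalise the
reported sampling means of 3.8 and 37 days); subjects missing either
window are excluded with a logged reason. Distances are related to days
preterm by Spearman correlation.

## Correlation network

Gating makes some parameter pairs arithmetically dependent (a subset
and its complement within one parent gate). Declared pairs are pruned
by keeping the first-listed member; the relation must be acyclic.
Pairwise Spearman correlations (mid-rank ties, pairwise-complete) over
the pooled longitudinal samples become edges at |ρ| ≥ 0.3 and
p < 0.008; parameters with no passing edge drop out. Pooling ignores
within-subject dependence at this stage — the intra-individual
procedure below is the stricter alternative and can be applied to
immune–immune pairs through the same binning functions. p-values use
exact permutation enumeration at n ≤ 10 and the t approximation above.

## Microbiome dynamics

Diversity is the inverse Simpson index computed from **all** taxa; the
\>1% mean-abundance filter applies only to which families are described
individually, and "never colonised" means no sample of a subject
exceeded 1% (strict) for that family. Per-subject series reduce to
Theil–Sen slopes — the median of all pairwise slopes, reported per week
(days × 7). Note that with only 4 points a single outlier corrupts 3 of
the 6 pairs and the estimator is *not* robust; from 5 points a lone
outlier is rejected exactly. Group summaries are weighted medians
(lower-median tie rule; weights = number of contributing samples), with
weighted means alongside.

The weighted Mann–Whitney contrast treats weights as replicate
multiplicities: pooled observations get weighted mid-ranks (an
observation of weight w occupies w rank slots), the statistic is the
weighted rank sum of one group, and the null distribution comes from
randomly relabelling which (value, weight) units belong to that group.
The two-sided p counts permutations at least as far from the exact null
mean of the statistic as the observed value, with +1 smoothing:
(count + 1)/(n_perm + 1). Centering on the *analytic* null mean rather
than the empirical permutation mean matters: the statistic lives on a
lattice, and an estimated centre wobbles across lattice midpoints and
biases the two-sided count. With equal weights the test agrees with the
classical exact Mann–Whitney to Monte-Carlo accuracy. Only
Enterobacteriaceae is slope-tested across groups by default — it is the
only family consistently abundant in all groups; other families get
descriptive slopes only.

## Intra-individual immune–microbiome link

Blood and stool series are matched by binning age into half-open 5-day
windows anchored at day 0 ([5k, 5k+5)), averaging multiple samples per
subject-bin; a pair of values exists only where a subject-bin holds
both. Binning is idempotent. Spearman correlation is then computed
within each subject alone (subjects need ≥ 4 matched bins — exact
enumeration of the Spearman null is degenerate below 4 informative
points; the threshold is configurable). A pair is *significant* only if
every included subject yields p < 0.2; the implied family-wise level
under independent per-subject nulls is 0.2^k for k included subjects
(0.008 at k = 3), reported alongside, with k always taken from the data
rather than fixed. The mean correlation across subjects is unweighted.

This criterion is deliberately conservative, and its power decays
geometrically in k: at a true within-subject ρ of 0.6 with 8 matched
bins, each subject passes the 0.2 gate with probability ≈ 0.63, so ten
subjects jointly pass ≈ 1% of the time. The recovery test therefore
plants a strong association (ρ = 0.9, 12 bins per subject) to
demonstrate detection, and the global-null experiment verifies the
false-flag rate stays below 0.2^k. On realistic effect sizes the
procedure is expected to flag few pairs — that behaviour is the method,
not a defect.

## Clinical-group contrasts

The group model extends the single-group mixed model with fixed group
main effects and group × age interactions against the stable reference
(all reported contrasts are versus stable), keeping the per-subject
random intercept and slope. Wald p-values are starred as in the figure
conventions; no additional multiplicity correction is applied across
parameters at this stage — a documented limitation of the presentation
it mirrors. Groups with a single subject are estimated but flagged
unreliable. Bacteraemia annotations (none / suspected / CoNS /
other_confirmed) relabel subjects into strata for finer fits.

## Synthetic cohort generator

The generator emulates the derived tables of the study design: 39
subjects (stable 10 / unstable 16 / BCM 13; microbiome subsets
10/13/11), roughly weekly sampling with a mean of eight blood samples
per subject starting on day 1–7, 186 immune parameters, and nine adult
donors. Immune values follow
`adult_mean·2^lfc + drift·(age/7) + b0 + b1·(age/7) + noise`, clipped
to the legal range of the parameter kind; per-parameter adult means and
birth log2 deviations are drawn once per seed, and the default drift
closes the birth-to-adult gap linearly over ~12 weeks. Birth levels are
kept inside [1, 90] % so that no parameter saturates at a clip bound —
a saturated series is constant and has no rank structure. Noise scales
(random intercept 0.5, random slope 0.15, measurement 1.0, all in
adult-SD units) were chosen once as plausible for flow-cytometry
frequency data.

Rank-correlated parameter pairs are generated through a Gaussian copula
with latent Pearson r = 2·sin(πρ/6), the closed-form calibration that
makes the latent normal's Spearman correlation equal the target ρ; an
infeasible (non-positive-definite) correlation set fails before any
sampling. Parameters participating in a planted correlation are held
stationary — no drift or subject random effects — because any shared
systematic structure would push the pooled rank correlation away from
the copula target; the planted value is then recovered unbiasedly
(±0.05 at ≥ 200 pooled samples, by test). The coupling is rank-based
only: marginal distributions are unchanged by imposing correlation.

Taxa tracks give Enterobacteriaceae a starting share of 75% moving at
the group's configured slope per week (defaults −5.6 / +0.16 / +0.38
%/week for stable / unstable / BCM) plus noise; the remaining mass is
split across 11 minor families such that the composition's inverse
Simpson matches the group's linear diversity trend wherever that is
compositionally feasible — dominance caps achievable diversity at
1/p², so the target is clipped into the feasible band (with a logged
count) when the two trends conflict. For exact diversity-slope recovery
the generator therefore also has a diversity-track mode emitting scalar
series `y = intercept + slope·(age/7) + N(0, 0.5)` directly (defaults:
intercept 2.5; slopes 0.56 / 0.035 / 0.053 U/week); these scalar tracks
can dip below the compositional floor of 1 in extreme draws, which is
accepted as the price of an exact linear ground truth.

A `prematurity_drift` knob scales each subject's immune drift with how
many days preterm they were born, giving the geometry stage a cohort
where trajectory distance should correlate with prematurity.

What the generator does **not** emulate: compositional count noise and
sequencing depth, antibiotic-driven regime shifts, bimodal colonisation
patterns, missing-panel structure in the immune data, or any mechanistic
immune–microbiome coupling. Passing recovery tests therefore show the
estimators recover the statistical structure they assume — not that the
pipeline is robust to every artefact of real cohort data.

## Pipeline and reproducibility

Stages run in dependency order from one config; the global seed fans
out per stage as SeedSequence([seed, stage_counter]) with a fixed
counter per stage name, so toggling one stage never shifts another's
draws. All randomness (generator, permutation tests) is seeded;
identical config + seed yields byte-identical CSVs. The all-pairs
network, link cross-product and per-parameter mixed-model stages are
quadratic or costly in the parameter count, so the pipeline caps them
(40 / 10 / 20 parameters by default, configurable to all); the library
functions themselves have no caps.

## Problem sizes in the test and acceptance experiments

Recovery experiments use 50 replicate cohorts for the slope targets
(10–13 subjects × 15 weekly samples in diversity-track mode; 10
subjects × 8 samples in taxa mode), 10^5 permutations for the group
contrast, and 10 replicate cohorts of 39 × 8 samples for the planted
rank correlations (reported as the across-replicate mean, which
estimates the same quantity as a single cohort with ~3× smaller
standard error). These sizes were chosen so each experiment completes
in seconds while leaving Monte-Carlo error well inside the tolerance it
is checked against.
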