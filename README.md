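# neotraj

Longitudinal immune-development and microbiome-dynamics analysis for
preterm-infant cohorts.

Babies born before 32 weeks of gestation are sampled repeatedly during
their stay in neonatal intensive care: flow-cytometry panels measure
~186 immune parameters per blood sample, and 16S sequencing of stool
yields family-level bacterial relative abundances. `neotraj` implements
the statistical pipeline for asking, from such derived tables:

* how far each immune parameter starts from the adult level and how it
  moves with postnatal age;
* whether whole immune profiles follow a shared developmental
  trajectory, and whether babies born earliest travel furthest along it;
* which immune parameters co-vary across the cohort;
* how gut-microbiome diversity and the dominant Enterobacteriaceae
  family progress in clinically stable babies versus unstable babies and
  babies born to mothers with chorioamnionitis (BCM);
* whether immune and microbiome series co-vary *within* individuals.

It is aimed at biostatisticians and computational immunologists working
with longitudinal neonatal cohort data, and ships a synthetic cohort
generator so every stage has a ground-truth recovery test without any
patient data.

## Methods at a glance

**Adult deviation.** For parameter $j$, the birth-side displacement is
$\mathrm{log_2FC}_j = \mathrm{median}_i\, \log_2\!\big((x_{ij}^{\text{first}}+\varepsilon)/(\tilde a_j+\varepsilon)\big)$
against the adult median $\tilde a_j$, with a two-sided Wilcoxon
rank-sum test and Benjamini–Hochberg correction across parameters.

**Longitudinal slopes.** Group-level change with postnatal age $t$ uses
a linear mixed model
$y_{it} = \beta_0 + \beta_1 t + b_{0i} + b_{1i} t + \varepsilon_{it}$
with a random intercept and slope per baby; sampling density weights
babies through their row counts. The sign pair
$(\mathrm{log_2FC}, \hat\beta_1)$ places each parameter in a quadrant
(start high/low × decreasing/increasing).

**Summary-measures microbiome analysis.** Per-sample diversity is the
inverse Simpson index $D = 1/\sum_k p_k^2$ over all families. Each
subject's series is reduced to a Theil–Sen slope (median of all pairwise
slopes, U per week); groups are summarised by the weighted median
(weights = samples per baby) and contrasted with a weighted Mann–Whitney
permutation test.

**Correlation network.** Spearman correlations over the pooled
longitudinal samples, after dropping the second member of each
gating-dependent parameter pair, become network edges when
$|\rho| \ge 0.3$ and $p < 0.008$.

**Intra-individual immune–microbiome link.** Blood and stool series are
matched in 5-day age bins; Spearman correlation is computed within each
subject alone, and a pair is flagged only when every included subject
gives $p < 0.2$. Under independent nulls the implied family-wise level
is $0.2^k$ — $0.008$ at $k = 3$.

## Worked example

Recover the group diversity slopes from synthetic cohorts generated at
the package defaults (stable 0.56, unstable 0.035 U/week):

```python
from neotraj import (SimConfig, generate_diversity_tracks, subject_slopes,
                     group_slope_summary, weighted_mann_whitney)

cfg = SimConfig(seed=7)
slopes = {}
for group, n in (("stable", 10), ("unstable", 13)):
    tracks = generate_diversity_tracks(cfg, group=group, n_subjects=n,
                                       n_samples=15)
    slopes[group] = subject_slopes(tracks, "inverse_simpson", "diversity")
    print(f"{group}: weighted median slope = "
          f"{group_slope_summary(slopes[group]):.3f} U/week")

p = weighted_mann_whitney(
    [s.slope_per_week for s in slopes["stable"]],
    [s.n_points for s in slopes["stable"]],
    [s.slope_per_week for s in slopes["unstable"]],
    [s.n_points for s in slopes["unstable"]],
    n_perm=100_000, seed=0)
print(f"weighted Mann-Whitney p = {p:.2e}")
```

prints

```
stable: weighted median slope = 0.548 U/week
unstable: weighted median slope = 0.019 U/week
weighted Mann-Whitney p = 1.00e-05
```

The stable group's recovered weighted-median slope (0.548) sits on the
generating 0.56 U/week, the unstable group's (0.019) on 0.035, and the
permutation test separates them at the smallest p reachable with 10^5
permutations.

The full pipeline runs from a single config:

```bash
neotraj run-all --out-dir results --seed 1      # simulate + all stages
neotraj microbiome --out-dir results --seed 1   # one stage, reads results/
```

Each stage writes tidy CSVs (`adult_deviation.csv`, `slopes.csv`,
`pca_scores.csv`, `edges.csv`, `diversity.csv`, `group_contrasts.csv`,
`link_results.csv`, ...) plus a `run_record.json` capturing config,
seed and version; identical config + seed gives byte-identical outputs.

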