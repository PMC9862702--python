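# premirdist

Distance distributions for pre-miRNA stem-loop sequences, and similarity
scoring of miRNA biomarker panels against them.

## The problem

miRNAs reported as biomarkers for two conditions are often strikingly
similar in sequence, and that similarity is used to argue for an
association between the conditions (disease–disease, disease–vaccine).
But "similar" is meaningless without a reference: a pairwise distance of
0.86 substitutions/site is only interpretable relative to the
distribution of *all* pairwise distances in the hairpin catalog.
`premirdist` builds exactly that reference distribution for a catalog of
pre-miRNA stem-loop (hairpin) sequences and uses it to rank the mean
pairwise distance of a biomarker panel as a percentile.

The package is for computational biologists and statisticians who want to

* compute all-pairs evolutionary distances over a hairpin FASTA catalog
  (e.g. the miRBase human stem-loops),
* derive and select a statistical model of those distances, and
* score published miRNA biomarker panels by how unusually similar their
  members are.

## The method

1. **Distances.** Every pair of hairpins is globally aligned
   (Needleman–Wunsch, NUC44-style scores: match +5 / mismatch −4, linear
   gap penalty 8). With L the scored aligned columns and X the differing
   ones, the observed difference fraction is p̂ = X/L (gapped columns are
   excluded by default). The one-parameter substitution correction

   K = −(3/4)·ln(1 − (4/3)·p̂)

   assumes all four nucleotides substitute with equal probability; K
   diverges as p̂ → 3/4 ("saturation"), and saturated pairs are flagged,
   never silently clamped. An n-record catalog yields the condensed
   vector of n(n−1)/2 distances.

2. **Distribution fitting and selection.** Four candidate families are
   fitted to the distance data: normal N(μ, σ²), exponential Exp(λ), the
   piecewise-linearly smoothed empirical CDF, and a Gaussian-kernel
   density estimate (unbounded support). Each fitted model exposes
   `cdf`, `quantile` and `sample`. Families are ranked by a two-sample
   Kolmogorov–Smirnov test of an n_check = 66 sample drawn from each fit
   against the data; on real hairpin catalogs the skewed, heavy-tailed
   distances reject the parametric families and select the KDE/ECDF.

3. **Percentiles and panels.** The selected model is tabulated at
   q = 5, 10, …, 100 % (q = 100 is the maximum observed distance). A
   biomarker panel of m names is resolved to stem-loop records, its
   m(m−1)/2 distances computed, and the percentile rank 100·F(mean)
   reported; a panel is called similar when that rank is strictly below a
   user-chosen threshold percentile.

## Worked example

```python
import numpy as np
import premirdist as pm

catalog = pm.study_catalog()                  # 160 synthetic hairpins
distances = pm.pairwise_distances(catalog)    # 12,720 distances
model = pm.DistanceDistribution(distances.values)
selection = model.select(n_check=66, seed=1)
print(selection.summary())
```

```
model selection (two-sample KS, n_check = 66, seed = 1)
     family                                              parameters  ks_statistic      p_value
        kde kernel=normal; bandwidth=0.0326467; support=unbounded ...      0.062854 9.420432e-01
       ecdf n=12696; nodes=1431; smoothing=piecewise-linear (midpoint ...  0.092176 5.964264e-01
     normal                             mu=0.640046; sigma=0.291009       0.207925 5.570377e-03
exponential                                mean (1/lambda)=0.640046       0.359075 3.986855e-08
```

The nonparametric families fit (p ≈ 0.94 and 0.60); the normal and
exponential fits are rejected — the distance data are skewed and
heavy-tailed, so a symmetric or mode-at-zero model cannot track them.
Scoring a 12-member panel against the selected model:

```python
report = pm.analyze_panel(catalog.ids[:12], catalog, selection.best_fit,
                          species_prefix="syn-mir-", threshold_p=30.0)
print(report.summary())
```

```
panel of 12 miRNAs -> 66 pairwise distances
  mean distance      = 0.732762
  range              = (0.169254, 1.64792)
  percentile of mean = 73.61
  verdict at p<30: not similar
```

The published percentile table for the human catalog ships with the
package, so the printed-table lookup rule works without recomputing
anything: a pairwise distance of 0.81 sits nearest the tabulated 15th
percentile (0.8093), i.e. the pair is more similar than 85 % of all
human hairpin pairs:

```python
from premirdist.reference import reference_quantile_table
pm.percentile_of(None, 0.81, mode="nearest-table",
                 table=reference_quantile_table())   # -> 15.0
```

A `premirdist` console script wraps the same workflow
(`distmat`, `fit`, `select`, `quantiles`, `panel`, `run`, `fixtures`);
`premirdist run --catalog hairpin.fa --out results/` executes all stages
with a cached distance matrix.

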