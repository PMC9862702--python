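# Methods

## Distance model

Pairwise distances are one-parameter substitution distances
K = −(3/4)·ln(1 − (4/3)·p̂), where p̂ = X/L is the observed fraction of
differing nucleotides between two globally aligned stem-loop sequences.
The model assumes the four bases {A, C, G, U} substitute for one another
with equal probability and sites evolve independently; it is the simplest
correction for multiple hits and the standard first choice for short
non-coding RNA comparisons. X and L are kept as exact integers inside
`AlignmentSummary`, so p̂ is a rational number converted to floating point
only when the correction is applied.

### Alignment

Hairpins are unequal in length (roughly 50–180 nt), so each pair is
aligned end to end by Needleman–Wunsch before counting sites
(`Bio.Align.PairwiseAligner`). Default scoring is NUC44-style restricted
to the four unambiguous bases — match +5, mismatch −4 — with a linear gap
penalty of magnitude 8 (open = extend). All four numbers and the gap
policy are configurable; published grand statistics for the human catalog
depend on the reference implementation's exact alignment defaults, so
agreement beyond ~1 % cannot be promised by any re-implementation and the
parameters are deliberately exposed.

Columns containing a gap are excluded from both L and X by default
(p-distance over ungapped columns); `gap_columns="mismatch"` instead
counts every aligned column and treats gapped ones as differences. Pairs
are canonicalized (sorted by sequence) before alignment so (L, X) is
symmetric even when the alignment optimum is not unique; Biopython's
first-traceback alignment makes results reproducible run to run.

One consequence worth knowing: for two equal-length sequences differing
at a fraction f of sites, the substitution-only overlay is *not* always
the optimal alignment. Converting two mismatches into a short
insertion–deletion pair gains 2·9 = 18 score units against a 16-unit gap
cost, so from f ≈ 0.1 upward the optimizer occasionally recovers
compensating gaps and reports p̂ slightly below f. The exact
planted-mutation oracle in the tests therefore pins the alignment to the
gapless optimum with prohibitive gap penalties; under default penalties
the tests assert p̂ ≤ f.

### Saturation

K is undefined for p̂ ≥ 3/4. Such pairs are stored as +inf with a
parallel `saturated_mask` rather than clamped or dropped silently: a
catalog's extreme right tail (the published human maximum ≈ 27 is a
near-saturation artifact, p̂ = 0.74999…) carries real information about
low-complexity repeats, and a hidden cap would distort every downstream
moment. Saturated pairs are excluded (with a logged count) when fitting
distributions and when averaging panel distances; an explicit cap is
available for users who prefer a finite substitute.

## Distribution fitting

`DistanceDistribution(values)` is the model object; `fit(family)` returns
a results object with `params`, `cdf`, `quantile`, `sample` and
`summary()`.

* **normal** — μ is the sample mean, σ the n−1 sample standard
  deviation (at catalog scale the n vs n−1 distinction is far below
  print precision). A zero-variance sample is flagged degenerate and
  treated as a point mass.
* **exponential** — mean 1/λ is the sample mean (maximum likelihood).
* **ecdf** — the step estimator F̂(x) = (1/n)·Σ 1{xᵢ ≤ x} is exposed as
  `step_cdf`; the working CDF interpolates linearly through midpoint
  nodes (x₍ᵢ₎, (i − ½)/n) (ties share one node at
  (c_before + ½·count)/n), clamped to 0 strictly below the minimum and 1
  at/above the maximum. The midpoint (Hazen) convention is the one under
  which the two-point fixture {1, 2} gives cdf(1.5) = ½; the boundary
  clamps introduce jumps of ½n⁻¹ at the extremes, negligible at any
  realistic n. Quantiles invert the same interpolant; sampling is
  inverse-CDF.
* **kde** — Gaussian kernels, unbounded support:
  F(x) = (1/n)·Σ Φ((x − xᵢ)/h). Mass below zero is accepted as a model
  artifact rather than clipped, matching the reference fit's unbounded
  support. `bandwidth="auto"` applies the normal-reference rule
  h = 1.06·min(sd, IQR/1.349)·n^(−1/5). The published reference
  bandwidth for the human catalog, 0.00973513, ships as
  `REFERENCE_BANDWIDTH`; it is far below the normal-reference value
  (≈ 0.026 for those data) and its derivation is not stated with the
  published table, so it is provided as a constant, not a rule.

  For n > 10,000 the CDF is evaluated on a 2¹⁵-point grid spanning the
  data ± 5h: points are linearly binned (weight split between adjacent
  nodes, keeping the error second order in the grid step), the density
  obtained by FFT convolution with a ±8h kernel window, and the CDF by
  trapezoidal accumulation. At the default resolution the grid step is
  ≪ h/10 and the observed CDF error against exact summation is below
  5×10⁻⁵; an `exact=True` flag forces full summation. Sampling never
  uses the grid: a data point is drawn uniformly and Gaussian noise of
  scale h added.

## Model selection

For each candidate family, an n_check-point sample is drawn from the fit
and compared with the data by the two-sample Kolmogorov–Smirnov test
(exact D over pooled points, asymptotic p-value at effective size
n₁n₂/(n₁+n₂), via `scipy.stats.ks_2samp(method="asymp")`); families are
ranked by descending p-value. n_check defaults to 66 to mirror the
reference analysis; a KS comparison at that size has low power, which the
model object surfaces with a warning for anything smaller — small
p-value differences between the well-fitting families are noise, and
only the gross parametric-vs-nonparametric separation is meaningful.
Child seeds for the per-family draws derive deterministically from the
single selection seed.

## Percentiles and panel scoring

The quantile table evaluates the selected model at q/100; q = 100 is
defined as the maximum *observed* distance, the only convention
consistent with tabulating an unbounded-support KDE. Two percentile
modes exist because both appear in practice: `continuous` (100·F(d),
used for panel means) and `nearest-table` (the printed-table rule: the
tabulated q whose value lies closest to d, ties to the smaller q).

A panel is scored by resolving its printed names against the catalog,
computing its m(m−1)/2 distances, and taking the percentile of the mean
of the finite ones. Names resolve case-insensitively, tiered: exact
identifier, then trailing locus suffix (-1/-2/-3), then trailing arm
letter (a/b); ambiguity is always recorded, the default policy takes the
lexicographically first candidate with a warning, and a user-supplied
name→identifier TSV overrides everything — published panels rarely state
which stem-loop locus was meant, so the choice must be auditable and
correctable. Two names resolving to the same stem-loop are kept as
distinct members (warned, not de-duplicated) so that pair counts match
the printed panel sizes. The similarity verdict is strict:
percentile < threshold; no global threshold is recommended, the user
must supply one.

## Synthetic data

`generate_fixture_catalog` draws i.i.d. sequences (lengths uniform on a
range, bases from a given composition); `plant_mutations` substitutes an
exact number of positions (never to the same base, no indels), so the
Hamming fraction between original and mutant is known by construction —
the oracle for the p̂ → K chain.

`generate_clustered_catalog` emulates the two features of real hairpin
catalogs that shape their distance distribution: paralogous families
(each ancestor founds a geometric-size family of copies mutated at a
fraction drawn from a range — the small-distance shoulder, as with the
let-7 or mir-515 families) and low-complexity sequences (a fraction of
families drawn with one base dominant — their unlike pairs are
mismatch-saturated, producing the flagged +inf pairs and heavy right
tail; their like pairs are spuriously close). The standard study
conditions (`study_catalog`) are 160 records, lengths 60–120 nt, mean
family size 2.5, mutation fractions 0.02–0.35, 15 % biased families at
dominant-base frequency 0.7, chosen once so that the synthetic distance
data reproduce the qualitative signature of the real catalog's: a
concentrated skewed bulk (skewness ≈ 2.7), a family shoulder, saturated
pairs, and a standard deviation inflated well above the bulk spread.
This is what passing tests demonstrate: the machinery ranks smooth
nonparametric fits above parametric ones *for data with that signature*.
They do not certify the published human-catalog numbers, which depend on
real sequences and on the reference toolbox's alignment defaults; those
checks run only when the real catalog FASTA is provided
(`data/hairpin_hsa.fa`), since it is external data that cannot be
generated. Synthetic sequences are i.i.d. within composition — no stem
self-complementarity, conserved seed motifs, or GC gradients — so
absolute distance values are not comparable with real catalogs.

The study size of 160 records (12,720 alignments, a couple of seconds)
keeps the full suite interactive while leaving every distribution fit
comfortably in its large-sample regime.

## Numerical choices

* Distances are cached to a self-describing TSV keyed by the identifier
  list and an alignment-parameter hash; stale caches are detected and
  recomputed.
* Alignment tie-breaks follow Biopython's fixed traceback preference,
  plus pair canonicalization (above) — distances are bit-reproducible.
* KDE quantiles use monotone bisection (exact mode) or interpolation on
  the shared CDF grid, so quantile/CDF round trips hold to 1e-6
  (1/n for the ECDF's piecewise interpolant).
* All sampling uses `numpy.random.default_rng` with explicit seeds;
  pipeline stages derive child seeds from the single run seed.

## Known limitations

* Only the one-parameter substitution correction is provided (no
  two-parameter transition/transversion model), and no multiple
  sequence alignment or tree building.
* Exact reproduction of published six-digit catalog statistics is
  contingent on matching the reference toolbox's alignment defaults;
  this package documents and exposes, but cannot verify, that choice.
* The KS check at n_check = 66 has very low power; it reproduces the
  published ranking behavior but should not be read as a calibrated
  goodness-of-fit test.
* Mature-arm miRNAs (e.g. miR-21-5p) are out of scope: the tool operates
  on stem-loops only.
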