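# Methods

## Problem and hypotheses

Let X = (X_1, …, X_n1) and Y = (Y_1, …, Y_n2) be the expression profiles of
one gene set (p genes) in two phenotypes, i.i.d. with distributions F and
G.  The multivariate tests address H0: F = G (the N-statistic) or the
location-restricted H0: μ_x = μ_y (KS, WW) against two-sided alternatives.
The tests are *self-contained*: only the set's own genes enter, never the
complement.

## Multivariate tests on the minimum spanning tree

The N = n1 + n2 samples are points in R^p; all geometry uses Euclidean
distance on log2(1+x)-transformed normalized expression.

**MST.**  Kruskal's algorithm on the complete graph, with candidate edges
ordered by (weight, smaller node index, larger node index).  The ordering
makes the tree deterministic under ties — including the fully degenerate
case of duplicated samples — and is the only freedom the MST definition
leaves.  Correctness is tested against exhaustive enumeration of all
labeled spanning trees (Prüfer sequences) for N ≤ 6 and against an
independent library implementation for larger N.

**HDP ranking (KS test).**  The tree is rooted at a node of maximal
eccentricity, where geodesic distance is the number of tree edges on the
connecting path; nodes are then ranked by a depth-first traversal visiting
children in decreasing subtree height.  Both tie-breaks (root choice and
child order) use the smallest node index; they are isolated in one
function.  Two consequences worth knowing:

* On tie-free 1-D data the MST is the sorted path, the root an endpoint,
  and the ranking the sort order — so the KS and WW statistics collapse
  exactly to their classical univariate forms (property-tested).
* The two endpoints of a tree diameter always tie on eccentricity, and
  subtree heights are small integers, so the traversal is *not* invariant
  under relabeling the samples.  The WW and N statistics are relabeling-
  invariant; the KS statistic can change under a joint permutation of
  columns and labels.  The suite asserts exact invariance for WW/N and
  Monte-Carlo-level agreement of P-values.

**Statistics.**  KS: walking nodes in rank order, D = max_i |r_i/n1 −
s_i/n2| with r_i, s_i the group counts among the first i nodes; large D is
extreme.  WW: R = (number of deleted mixed-label MST edges) + 1, the count
of homogeneous subtrees; small R is extreme.  N-statistic:
`N = sqrt( n1 n2/(n1+n2) · [ S_xy/(n1 n2) − S_xx/(2 n1²) − S_yy/(2 n2²) ] )`
with S the distance sums over ordered pairs (within-group sums include the
zero diagonal).  The bracket is the sample energy distance and can be
negative in finite samples; it is clipped at zero before the square root.
Whether the n1 n2/(n1+n2) prefactor sits inside or outside the root is a
monotone reparameterization at fixed group sizes and cannot change a
permutation P-value; this package keeps it inside.

## Permutation P-values and tie conventions

Null distributions come from B uniformly random relabelings preserving
(n1, n2).  The per-set distance matrix — and for KS/WW the tree and its
ranking — is computed once; only labels are permuted (a pure optimization,
since distances do not depend on labels).  Two estimators are exposed:

* `ties="add-one"` (default of the reporting API): P = (b+1)/(B+1) with b
  the permuted statistics *at least as extreme*.  Valid by construction
  (never 0, never anti-conservative).
* `ties="strict"` (default of the simulation-study estimators): the plain
  proportion of permuted statistics *strictly more extreme* than the
  observation.

The distinction only matters for heavily tied discrete statistics.  D and
R take few values at N = 20, so the strict proportion is systematically
liberal — empirical Type I error near 0.10 at α = 0.05 — while the add-one
estimator is conservative for them.  The continuous N-statistic is
essentially tie-free and both conventions hold the nominal level.  The
simulation harness defaults to the strict convention because that is the
procedure of the comparative study it reproduces; analysts reporting
P-values for real data should prefer add-one.

Per-set permutation seeds are derived as (global seed + CRC32 of the set
name) mod 2³¹−1, so results are independent of set evaluation order and
any single set can be re-run in isolation.

## Normalizations

All four chains end in a linear-scale matrix passed through log2(1+x),
which damps outliers without creating negatives.

* **RPKM**: 1e9 · Y_ij / (L_i · N_j), L in bp, N_j the column sum.
* **TMM + RPKM**: scaling factors from the doubly trimmed (30% two-sided
  on the log-ratios M, 5% on the average log abundance A), inverse-
  asymptotic-variance-weighted mean of gene-wise log-ratios against a
  reference sample (the one whose upper-quartile count fraction is closest
  to the mean); genes with a zero count in either member of a pair are
  excluded from that pair.  Factors are geometric-mean-centred, multiply
  the library sizes, and RPKM follows with the effective sizes.  The trim
  fractions and reference rule are the published defaults of the method's
  reference implementation, against which the factors are cross-checked in
  a test.
* **QQN + RPKM**: each sample's order statistics are replaced by the
  across-sample mean order statistics; ties receive the mid-rank mean
  (the reference microarray convention; the source study does not state a
  tie rule).  Because quantile normalization ignores gene length, RPKM
  scaling follows, with the depth term using post-QQN column sums (the
  pre/post choice is not stated upstream; post is implemented and
  switchable by normalizing manually).
* **voom-like + RPKM**: offset log-CPM log2((Y+0.5)/(N+1)·1e6),
  back-transformed by the exact inverse 2^x(N+1)/1e6 − 0.5 floored at 0,
  then RPKM.  Precision weights are deliberately absent — they exist for a
  linear-model framework that is out of scope here.  Note the exact
  inverse makes this chain numerically identical to plain RPKM for
  non-negative counts; it is kept as a separate chain so the study
  machinery exercises the same pipeline shape a log-CPM workflow would.

A design consequence the suite documents: all simulated sets of one
experiment are stacked into one matrix before normalization, so TMM/QQN
see realistic library structure.  This couples sets through the shared
per-sample scaling, which leaves permutation tests exact per set but makes
rejection events mildly dependent *across* sets — empirical rejection
fractions therefore scatter slightly more between seeds than the binomial
standard error suggests.

## Gene-level combining

T = Σ_i H(p_i) with H the Fisher (−2 ln p), Stouffer (Φ⁻¹(1−p)) or Gamma
(G⁻¹_{w,1}(1−p)) transform.  The Gamma shape w and the soft truncation
threshold STT are linked by the fixed point w = G⁻¹_{w,1}(1−STT),
equivalently G_{w,1}(w) = 1−STT, solved by bracketing + Brent bisection to
relative tolerance 1e-6 (STT = 0.05 → w ≈ 0.0137; STT = 1/e → w = 1,
where GM is rank-identical to Fisher; STT → 0.5 is the Stouffer limit and
lies outside the solver's domain).  Small w makes T sensitive almost only
to tiny gene-level P-values — the transform of p = 0.2 is under 1% of the
transform of p = 1e-5 at w = 0.0137.

Gene correlations invalidate the parametric null of T, so the set-level
P-value is always a permutation estimate, with the univariate test re-run
inside every permutation.  The built-in univariate test is a two-sided
Welch t on log-normalized values (vectorized over genes, verified against
the standard library routine); any callable with the same signature can
replace it, e.g. to plug in externally computed per-permutation P-value
matrices.  Gene-level P-values are floored at 1/(B+1) and capped just
below 1 before the SM/GM transforms, which diverge at the endpoints.

## NB simulator

Counts are gamma-Poisson draws: λ ~ Gamma(1/φ, μφ), Y ~ Poisson(λ), giving
mean μ and variance μ(1+μφ) exactly (moment-tested); φ = 0 degenerates to
Poisson.  Each gene of a set draws its (μ, φ, L) from the pool without
replacement within the set, with replacement across sets.  For phenotype 2
the first ⌊γp⌋-floored-to-even genes get mean FC·μ; the generated counts of
the first half of those genes are then swapped between phenotypes, so half
the DE genes are down- and half up-regulated and expected per-sample totals
stay balanced (tested at FC = 3).

**Synthetic parameter pool.**  The real pool of the motivating study was
estimated from a human LCL dataset that is not shipped; the stand-in is
explicit and overridable (TSV with columns mu, phi, length):
μ ~ logN(4.0, 1.5) truncated to [1, 1e5] (median ≈ 55 counts, heavy right
tail typical of bulk RNA-Seq); φ = (0.04 + 2/μ)·logN(0, 0.35), the usual
decreasing mean-dispersion trend with a biological-coefficient-of-variation
floor around 0.2; L ~ logN(7.5, 0.7) truncated to [200, 1e5] bp (median
≈ 1.8 kb).  These values were chosen once as field-typical and are not
tuned.  A green simulation test therefore establishes calibration/power
*under this stated world* — it does not certify behaviour under real
library-size heterogeneity, gene-gene correlation within sets (genes are
simulated independently), batch effects, or zero-inflation beyond NB.

**Estimators.**  Type I error: FC = γ = 1, fraction of sets with P ≤ α.
Power: the same code path per (FC, γ) grid cell; an FC = 1 cell equals the
Type I estimate for a matched seed (tested).  Whole experiments are
normalized as one matrix (see above).  Runs are bit-identical for a fixed
seed.

## Study runner

Grid sweeps over (test × normalization × N × p) and (test × γ × FC) with
per-cell JSON caching keyed by a SHA-256 digest of the complete cell
configuration including seeds, so interrupted grids resume safely.  Bias
diagnostics for any results table: per detected pathway (P ≤ α) the size,
the fraction of DE genes (built-in Welch test + Benjamini-Hochberg at
0.05 — a stand-in for the moderated-t used upstream, recorded in the
output metadata), and the mean gene length; plus a two-sided Wilcoxon
rank-sum comparison of detected pathways' mean lengths against all
pathways' (flagged P = 1 when nothing or everything is detected).  Venn
cell counts of detections across methods complete the diagnostics.

## Numerical and interface choices

* Gene sets are matched to data by exact string ID; sets are intersected
  with the measured genes *before* the 10 ≤ p ≤ 500 size filter.
* Results tables have a fixed column order and input row order, so
  re-runs are byte-identical.
* The CLI (`mstgsa normalize|test|combine|simulate|type1|power|study`) is
  a thin layer over the library; the YAML study config is a flat
  key-value document mirroring `StudyConfig`.

## Known limitations

* The KS statistic's dependence on index-based tie-breaks (above) means
  cross-implementation agreement on D requires matching HDP tie rules.
* The gene-level route with *external* univariate tests that share
  information across genes (empirical-Bayes dispersion shrinkage) can
  break permutation exchangeability; the package recomputes only its
  built-in exchangeable test inside permutations and makes no calibration
  claim for plugged-in non-exchangeable tests.
* No competitive (set-vs-complement) tests, no rotation/parametric
  multivariate tests, no asymptotic P-values, no estimation of (μ, φ)
  from real counts.
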