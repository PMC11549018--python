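# Methods

## The cell-specific association score

For gene g and candidate enhancer e, every cell c receives a score measuring
whether the accessibility of e among cells transcriptionally similar to c (for
gene g) departs from its genome-wide level. The neighborhood of c is the k
cells (default k = 30, focal cell included) with expression of g closest to
c's; expression is compared on log1p library-size-normalized values (scaled to
the median depth), with raw counts available via `expression_values="raw"`.
With N_cge the number of neighborhood cells whose count at e is nonzero and
pi_e the fraction of all cells with a nonzero count at e, the null model is
N_cge ~ Binomial(k, pi_e). Accessibility is binarized for both quantities:
scATAC counts are near-binary and summing raw counts would conflate depth with
openness.

The test is exact (no normal approximation) and **two-sided by default**:
p = min(1, 2·min(P(X ≥ N), P(X ≤ N))). The null hypothesis is that
neighborhood accessibility is on par with the cell-wide average, and both
departures are evidence of coupling — in a cell whose gene is "off", the
neighborhood of a truly coupled pair is *depleted* of accessible cells. This
matters in practice: on synthetic on/off programs an enrichment-only tail
gives those cells p ≈ 1 and drives the median score of true pairs toward
zero (planted-pair AUROC 0.50 one-sided vs 0.99 two-sided under the default
generator); `alternative="greater"` remains available. P-values are floored
at 1e-300 before log10 so scores stay finite.

The pair score is s_ge = median over cells of −log10 p_cge (midpoint mean for
even C; mean aggregation optional). Neighborhood ties are broken by ascending
cell index, which makes results deterministic but means that on heavily tied
expression (raw counts) the scores are invariant to joint cell permutation
only up to tie-breaking; with tie-free expression the invariance is exact.

Adaptive neighborhood sizes are deliberately out of scope; n_cg = k fixed.

## Marginal correlation with matched-background null

The marginal score of a pair is the Spearman correlation (tie-corrected,
computed as Pearson on mid-ranks) between the gene's expression and the
peak's accessibility across cells. Raw correlations are biased by peak
properties, so significance is judged per pair: m = 200 background peaks are
drawn (seeded, without replacement) from the same accessibility-fraction
decile × width decile bin as the target, widening to neighboring bins
(Manhattan distance on bin indices) when the bin is sparse. GC matching would
require genome sequence and is not implemented. The observed correlation is
z-scored against the background correlations (with the same gene) and
converted to an upper-tail normal p-value; the benchmark score is −p. On
fully independent data the empirical rejection rate at alpha = 0.05 is ≈ 0.05
(measured 0.048–0.053 over 2000 pairs of 1000 cells; the suite asserts the
binomial 95% band).

## Sparse regression under stability selection

All three variants regress on the raw accessibility counts of the gene's
candidate enhancers, standardized (zero mean, unit variance) within each
subsample; responses are standardized the same way. Objectives are written
with a (1/C) squared-error loss; the weighted l1 problem is solved exactly as
a plain lasso after dividing each standardized predictor by its weight
phi_ge and back-transforming.

* **adaptive**: phi_ge = 1/max(co-accessibility, 1e-3). Co-accessibility
  comes from a user-supplied table when available; the built-in fallback is
  max(0, Spearman correlation) between the gene's promoter-peak accessibility
  and the enhancer's accessibility. Missing/non-positive scores get the
  maximal weight (1000).
* **sequential**: stage 1 regresses promoter accessibility on the enhancers
  (lasso); only strictly positive coefficients survive; stage 2 is a lasso of
  expression on the survivors.
* **multi_response**: expression and promoter accessibility are fit jointly
  with per-enhancer groups (beta_ge, alpha_ge) under
  lam1·|·|_1 + lam2·||group||_2 (the convex sparse-group form — the
  group *norm*, not its square — chosen because it zeroes whole groups, which
  is what "grouping" must mean for selection; the ridge-style reading of the
  penalty would never produce exact zeros). Solved by block coordinate
  descent with the two-level soft-threshold group update, warm-started along
  the path; coefficient-change tolerance 1e-10 for single fits, 1e-6 inside
  stability selection where only the selected/not-selected state matters.

Genes without a promoter peak (no peak overlapping the strand-aware window
[TSS−2000, TSS+200)) are skipped by sequential/multi_response with a warning.

**Stability selection.** Each gene's model is refit on 100 random subsamples
of size floor(C/2) over a grid of 30 log-spaced penalties from the
data-derived lambda_max (smallest penalty giving the null model, computed on
the standardized full data) down to 0.01·lambda_max. An enhancer's score is
the fraction of subsamples in which it is selected at any *admissible* grid
point, where admissible means the fit keeps at most q = ceil(sqrt(0.8·E))
enhancers active (config `max_active`). The cap is the standard per-fit
sparsity bound of stability selection's error control; without it the low end
of any wide grid selects every candidate and all frequencies saturate at 1.
For the two-penalty variants the grid is handled as: sequential — each stage
gets its own data-derived grid and selection is maximized over both
(survivor sets are deduplicated, so the cross product costs little);
multi_response — lam1 = 0.5·lam, lam2 = 0.5·lam along one path
(`sgl_alpha` exposes the split). Subsampling is seeded; identical seeds give
identical frequencies. Failed fits are dropped from the denominator.

## Distance adjustment and baseline

Any score table can be post-processed as s' = (s + eps)·exp(−d_ge/d0) with
eps = 0.05 and d0 = 200 kb; d_ge is |TSS − peak midpoint|. Scores on a
negative scale (marginal −p, baseline −d) are first shifted so the table
minimum is zero: eps only guarantees positivity for non-negative statistics,
and a negative s would make the decay promote distal pairs. The distance
baseline scores pairs by −d_ge.

A property worth stating plainly: the adjustment is **not ranking-neutral**
when truth is independent of distance. The factor spans exp(−2.5) ≈ 12×
across a ±500 kb window, so a true pair near the window edge falls below a
proximal decoy whenever (s_true+eps)/(s_decoy+eps) < exp(Δd/d0). On
synthetic data with distance-uniform planting the adjustment *costs* every
method 0.07–0.23 AUROC; it helps exactly when true pairs are
distance-biased toward the TSS — which is what curated gold standards show.
One acceptance test asserts near-neutrality under uniform planting and is
expected to fail; it documents this property rather than a defect.

## Candidate enumeration, filtering, conventions

Coordinates are BED-style 0-based half-open; distances in bp. A peak is a
candidate for a gene when its interval overlaps [TSS − 500 kb, TSS + 500 kb]
(interval overlap, not midpoint containment; `window` configurable). The
promoter peak is the largest-overlap peak in the strand-aware window
[TSS−2000, TSS+200); it supplies promoter accessibility and is excluded from
the candidate set to avoid self-association. Strand affects only the promoter
window, not d_ge.

Gene filtering keeps genes that (i) are expressed (count > 0) in strictly
more than 5% of cells, (ii) rank within the top 8000 genes by variance of
log1p-normalized expression (raw-count variance via config), and (iii) have
at least 3 candidate peaks. Failure of all genes raises with a per-rule
attrition report.

## Benchmarking

Gold standards define no negatives, so labeling restricts them to detected
enhancers: a candidate pair is positive when its peak overlaps a gold
enhancer recorded with the same gene, negative when the peak overlaps some
gold enhancer but none of its records name the candidate gene, and
not-classified otherwise (excluded from metrics). Multiple gold files can be
aggregated as a union: validated by any file counts as positive. AUROC is the
tie-corrected rank statistic, AUPR the step-wise (non-interpolated) average
precision; both are cross-checked in the suite against exhaustive
pair-counting/threshold-sweep oracles.

Replicate reproducibility maps replicate-2 scores onto replicate-1 pairs by
enhancer interval overlap within the same gene (one-to-many allowed; max
aggregation by default, mean optional), drops pairs with exactly-zero
statistics in either replicate, and counts the overlap of the two top-n sets
over a grid of n. Top-n ties break on (score desc, gene id, peak start).
Identical replicates trace the diagonal overlap(n) = n.

External per-tile FDR tables are imported as pair scores via
max(1 − FDR) over same-gene tiles overlapping the enhancer; co-accessibility
tables feed the adaptive weights. Neither tool is reimplemented.

## Synthetic data generator

The generator emulates the data the methods consume, not a specific assay:
negative-binomial expression (mean 5, size 8 — overdispersed but detectable
for top-variable genes) with 10% multiplicative dropout, Bernoulli 0/1
accessibility (base rate 0.1; promoter base 0.2), genes spaced 2.1 Mb apart
on one chromosome so ±500 kb windows are disjoint, 10 candidate peaks per
gene plus 2 out-of-window distractors, peak midpoints ≥ 900 bp apart so
peaks are disjoint (as peak callers produce), and one planted enhancer for
half the genes. For a planted pair a latent per-cell activity U_c drives
both modalities: P(accessible) = base + strength·U_c (clipped) and
E[expression] = mean·(1 + strength·U_c). U_c is bimodal — half the cells
carry the program with U ~ Uniform(0.5, 1), the rest have U = 0 — an on/off
regulatory program with graded "on" activity. A continuum U ~ Uniform(0, 1)
at the same strength yields pair correlations of ~0.07, undetectable at
benchmark sample sizes, and places the median cell exactly at the null,
which says more about that latent choice than about any method. Optional
sub-populations restrict each planted coupling to one population.
`planted_placement="near"` draws planted distances from 5–50 kb and decoys
from 100–490 kb (default: both uniform over 5–490 kb). The derived gold
standard contains the planted enhancers (a configurable fraction, emulating
detection limits) plus a fraction (default 0.3) of decoy peaks recorded with
a *different* gene — without these, the detected-enhancer rule would label no
negatives, since gene windows are disjoint.

What the generator does not emulate: fragment-level scATAC structure, batch
effects, doublets, co-expression confounding between genes, chromatin-domain
correlation between nearby peaks, and distance-dependent coupling strength.
Passing tests therefore show the estimators recover the planted generative
coupling under realistic sparsity — not that any method resolves the harder
ambiguities of real multiome data.

## Numerical choices and problem sizes

Exact Binomial tails via the regularized incomplete beta (scipy), verified
against direct pmf summation to 1e-12 relative error for all n ≤ 64. Lasso
solutions satisfy subgradient (KKT) conditions within 1e-6 and match an
independent coordinate-descent oracle's objective within 1e-6. Degenerate
cases: constant vectors score 0 (correlation) or warn with p = 1 (degenerate
background, sd < 1e-12); empty survivor sets are valid all-zero fits;
zero-variance columns standardize to zero. The test suite and acceptance
script run the planted-coupling study at C = 500, G = 50, 10 peaks/gene —
large enough that every method separates planted pairs cleanly, small enough
to iterate on — and calibration at C = 1000 over 2000 null pairs; the
stability selections (100 subsamples × 30 grid points per gene) dominate the
~7-minute acceptance runtime.

## Known limitations

Neighborhood construction is O(C²) per gene (distance matrix + stable
argsort); fine to a few thousand cells, beyond which a sorted sliding-window
construction would be the next step. The marginal null assumes background
correlations are exchangeable with the target's under H0; strong
peak-intrinsic structure not captured by (accessibility fraction, width)
would miscalibrate it. Selection frequencies are reported raw — the
family-wise error calibration of stability selection is logged but not used
for thresholding, since benchmarking consumes rankings. Metacell aggregation
is intentionally absent: the per-cell Binomial null does not survive
aggregation of cells into metacells.
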