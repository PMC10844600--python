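# Methods

This note records the models and procedures `hicmap` implements, the
defaults and why, the behavior of the synthetic generator that powers the
test suite, and the numerical choices made where the design was open.

## Data model and coordinates

Contact data live in a `ContactMap`: a fixed-resolution genome partition
(`BinTable`) plus an upper-triangular sparse record set (`InteractionSet`)
with named score layers, always including raw `count` and optionally
`balanced`, `expected`, `oe` and user-injected layers.  Internally all
intervals are 0-based half-open; user-facing region strings
(`"chrII:1001-2000"`) are 1-based inclusive, the genome-browser
convention.  The diagonal is stored once; dense coercion mirrors the upper
triangle without doubling it.  Counts coerce to dense with 0 for absent
records, all other layers with NaN, so "no data" and "zero signal" stay
distinguishable.  Missing balancing weights are NaN, never 0, so filtered
bins are distinguishable from bins that merely balance to small weights.

In-memory `zoom` coarsens by integer factors only, summing raw counts into
parent bins (the fine-to-coarse bin map is monotone, so upper-triangularity
is preserved and each record folds exactly once).  Balanced and derived
layers are dropped and flagged stale rather than approximated: weights are
resolution-specific and must be recomputed.

## File formats

The `.cool`/`.mcool` reader and writer follow the cooler HDF5 schema
(`chroms`, `bins`, `pixels`, `indexes` groups; region queries go through
the `bin1_offset` index so only the needed pixel rows are read).  Weights
are stored multiplicatively (`balanced = w_i * w_j * count`); a file
attribute (`divisive-weights = False`) records the convention.  Counts
round-trip bit-exactly as integers; weights as float64.  HiC-Pro matrix
files use 1-based bin ids (that tool's documented convention), mapped to
0-based global ids on read.  4DN `.pairs` positions are 1-based per the
specification and converted at binning time; the genome layout is rebuilt
from `#chromsize:` header lines, gzip is detected from magic bytes, and the
body is streamed.  The binary `.hic` container is deliberately not parsed —
it is an undocumented format with low marginal value at desk scale — and
opening one raises an error that points at `.cool` conversion.

Pair filtering at binning time: PCR duplicates are records identical in
(chrom1, pos1, strand1, chrom2, pos2, strand2); optional `min_cis_distance`
drops short-range cis pairs (self-religation artifacts).  Kept/dropped
tallies land in the map metadata so mass-conservation checks are possible
downstream.

## Balancing

Iterative correction (ICE): starting from unit weights on valid bins,
each round divides `w_i` by its mean-scaled balanced marginal; the loop
stops when the variance of mean-scaled marginals over valid bins falls
below `tol` (default `1e-5`) or after `max_iter` (default 200) rounds.
On exit the weights are rescaled so the mean balanced marginal is exactly
1.  Balancing runs genome-wide (cis + trans) by default — the common
choice — with a `cis_only` switch.  Non-convergence flags the result but
still returns weights.  Doubling all counts scales weights by `1/sqrt(2)`
and leaves the balanced pattern unchanged; multiplying any row/column by a
positive factor leaves the balanced matrix invariant (this is the bias the
procedure exists to remove).

Bin filtering precedes balancing (and is auto-invoked): bins with zero
marginal, and bins whose log10 marginal falls more than `mad_max`
(default 5) robust standard deviations below the per-chromosome median,
are excluded.  The robust standard deviation is `1.4826 x MAD`, the
Gaussian-consistent scaling.  The scaling matters: on clean maps the MAD
of log marginals is small (~0.015), and unscaled-MAD thresholds start
filtering the genuinely lower-coverage bins that flank insulated domain
boundaries — biology, not artifact.  With the scaled form those bins
survive while unmappable/artefactual bins (orders of magnitude low) are
still caught.

A note on stopping: with the variance-based stopping rule, individual
marginals deviate from 1 by about `sqrt(tol)` at exit, not `tol`.  The
test suite therefore checks marginal uniformity on that scale; demanding
deviations of order `tol` itself would require a max-deviation stopping
rule the variance criterion does not imply.

## Expected signal, O/E and correlation

`E(d)` is the raw per-offset mean of the balanced layer over valid bin
pairs, counting absent records as zero — so
`sum_d n_pairs(d) * E(d)` equals the total balanced mass exactly, an
identity the tests assert.  No smoothing is applied by default (an
optional log-offset rolling mean exists for sparse far diagonals is not
needed at the depths exercised here).  Trans expectations are per
chromosome pair.  O/E divides by the broadcast expectation; a zero
expectation yields NaN, never infinity.

Correlation maps are Pearson correlations of O/E rows computed per
chromosome with pairwise-complete observations (>= 3 shared positions).
The `d = 0` diagonal of the O/E input is excluded before correlating to
avoid self-inflation; the output diagonal is set to 1 for valid bins.

## Compartments

E1 is the leading (largest-eigenvalue) eigenvector of the per-chromosome
O/E correlation matrix — the correlation matrix, not O/E directly, because
the checkerboard ("plaid") pattern is a property of interaction *profiles*.
It is scaled by `sqrt(|lambda_1|)` so its magnitude reflects explained
structure, and its per-chromosome sign is anchored so the correlation with
a user-supplied phasing track (GC content, gene density, or the planted
states in tests) is positive; without a phasing track the sign is
arbitrary and a warning says so.  Chromosomes with fewer than 10 valid
bins are left missing.

## Insulation and borders

For window `w` bins, the raw score at bin `i` is the mean balanced signal
over the `w x w` diamond upstream x downstream of `i` (the bin's own
row/column excluded); `IS = log2(raw / chromosome mean of raw)`, defined
only where the full diamond fits and at least 50% of its pixels are valid.
An all-zero diamond (a hard junction) is floored at half the smallest
positive diamond mean so its log score stays defined and maximally
insulating.  Borders are local minima of IS with prominence >= 0.1 (log2
units) found per contiguous defined segment; the prominence is reported as
the border score.  IS is invariant to global rescaling of the balanced
layer by construction.

## Loop detection

A single-template detector: within the requested cis distance band, each
pixel whose O/E exceeds 1 has its `(2k+1)^2` log-O/E patch (default
`k = 3`) correlated against a fixed template — a central Gaussian bump of
one-bin width on a flat background.  Candidates with correlation
`>= rho_min` (default 0.35) pass non-maximum suppression within
`min_separation` Chebyshev bins (default 2), strongest first.  This is a
deliberate simplification of trained multi-kernel detectors: one template,
no distance-matched background model, no FDR control.  It is adequate for
focal enrichments a few-fold above background and is documented as such;
detection count is monotone non-increasing in `rho_min`, and recall grows
with planted enrichment (both property-tested).

## Saddle summaries

Valid bins are split into `q` equal-count quantile groups by E1 (default
`q = 38`), ordered from strongest B to strongest A; the saddle matrix is
the mean O/E over records joining each group pair, cis-only by default,
with an optional minimum genomic separation (e.g. 5 Mb on real genomes) to
suppress distance-decay leakage near the diagonal.  Corner summaries
average O/E over the A/B sign classes under the same filter.  Equal-count
(not equal-width) quantiles keep group populations balanced under skewed
E1 distributions.

## Interaction statistics

* **cis/trans**: raw-count tallies; a trans contact is attributed to both
  partner chromosomes, so summing `n_trans` over chromosomes double-counts
  by construction (the genome-level fraction halves it).
* **P(s)**: log-spaced bins (factor 1.1 by default) from `min_s` to
  `max_s`; `P(s) = contacts in bin / (total cis contacts x pairable locus
  pairs in bin)`, a per-pair density comparable across chromosome lengths.
  For read-level pairs the pairable count is the continuous integral
  `sum_c (L_c - s) ds`; for binned maps it is the discrete bin-pair count
  at each offset — the discrete form matters because at small separations
  a log bin holds zero or one distinct offsets and the continuous
  approximation biases the slope.  The slope is a centered finite
  difference of log10 P against log10 s after a window-3 rolling mean;
  `fit_slope` additionally offers a least-squares fit over a range.
* **Scalogram**: per-bin score-weighted quantiles (default 25/50/75%) of
  the cis contact-distance distribution, capped at `max_s`; weights use
  balanced scores when available, raw counts otherwise.
* **Virtual 4C**: the summed score profile of a viewpoint's bins against
  the genome; normalization divides per chromosome so profiles sum to 1.
* **SCC**: per chromosome, dense cis count matrices are smoothed with a
  `(2h+1)^2` uniform filter (default `h = 1`); strata are bin offsets from
  1 to `max_s/resolution` (default 5 Mb); stratum correlations are
  combined with weights `n_k * sd_k(a) * sd_k(b)`, and the genome score
  averages chromosomes by bin count.  Self-comparison returns exactly 1
  (identical strata short-circuit the correlation, avoiding float
  round-off).  Zero-variance strata get weight 0.

## The synthetic generator

`synthesize_map` composes a per-pixel intensity
`Lambda_ij = decay * plaid * domain * loop * bias_i bias_j`:

* `decay(s) = max(s, resolution)^-alpha` in cis, uniform in trans;
* `plaid = 1 + gamma * state_i * state_j` for per-bin +-1 states, applied
  in cis and trans alike;
* `domain = delta` for same-domain cis pairs (domains never span
  chromosomes);
* `loop`: a Gaussian bump of peak height `eta` and one-bin width around
  each planted anchor pair (so detrended maps show O/E ~ eta at the
  anchor pixel);
* `bias`: an optional separable per-bin field.

Cis and trans blocks are scaled separately so their expected totals are
`cis_fraction * n_contacts` and the remainder; counts are independent
Poisson draws (asymptotically equivalent to multinomial at fixed total).
`synthesize_pairs` draws cis separations by inverse transform from the
truncated power law on `[s_min, s_max]` (separations are rounded before
position placement so `pos2` never leaves the chromosome), positions
uniform, trans pairs uniform, with optional PCR duplicates at a stated
rate.  Everything is a pure function of (spec, seed), and ground truth is
emitted in the same shapes the feature callers output.

What the generator does *not* emulate: restriction-fragment structure,
mappability gaps, copy-number variation, distance-dependent noise beyond
Poisson, nested/hierarchical TADs, or trans compartment geometry beyond
the plaid factor.  Passing tests therefore demonstrate correctness of the
algorithms under separable bias and Poisson counting noise, not robustness
to every artifact of real libraries.

### Study fixtures and their sizes

Fixture parameters used by the tests and the acceptance script, chosen
once as realistic desk-scale conditions:

* *Plaid fixture* (compartments, saddle): one 4 Mb chromosome at 10 kb,
  gamma 0.4, 20-bin (200 kb) alternating blocks, 1e6 contacts.
* *Domain fixture* (insulation): 540 kb at 2 kb, eight boundaries every
  60 kb, delta 3, 8e5 contacts — comparable to a deeply sequenced yeast
  segment; the insulation window is 10 bins (20 kb).
* *Loop fixture*: 800 kb at 2 kb, twenty anchors 16–100 kb apart at 5x
  enrichment, 3e6 contacts.
* *Bias fixture* (balancing): two chromosomes (1 Mb + 800 kb) at 5 kb with
  trans contacts (cis fraction 0.9) and a log-normal bias field of
  sigma 0.6 — roughly the order-of-magnitude spread a composite of
  mappability, GC and fragment-density biases produces on real maps.  The
  spread matters for the bias-recovery readout: log-weights also carry the
  deterministic chromosome-end marginal structure of the decay (sd ~0.05),
  which bounds the achievable correlation with the planted bias; a
  realistic bias amplitude keeps that bound near 0.996.
* *Concordance fixture* (SCC): two chromosomes at 10 kb, 4e6 contacts,
  with plaid (gamma 0.6) and domains (delta 2).  Structure is essential
  here, not decorative: on a pure-decay map the within-stratum intensity
  surface is flat, so the correlation between two independent thinnings is
  bounded by the ratio of shared Poisson variance to thinning variance
  (~0.8–0.9 at any depth) and SCC would measure nothing.  Real maps have
  strong within-stratum structure; the fixture mirrors that.
* *P(s) fixture*: 1e6 read pairs, exponent 1.5 on 10 kb–1 Mb, chromosomes
  >= 10 Mb so the `(L - s)/L` placement factor distorts the fitted slope
  by < 0.01.

## Rendering

All figures go through the matplotlib Agg backend.  Square heatmaps use
log10 color scaling for counts/balanced layers and a symmetric diverging
scale for signed layers (log2 ratios); a comparison map can occupy the
lower triangle; horizontal mode draws the rotated near-diagonal band.
Saddle heatmaps order groups from strongest B to strongest A.  SVG output
is byte-deterministic (fixed hash salt, date metadata stripped).  The
color normalization is exposed (`normalize_for_render`) so tests can check
the mapped array against an independent computation rather than comparing
image bytes.

## Known limitations

* Genome-wide (all-chromosome) correlation and eigenvector decomposition
  are per-chromosome only; no inter-chromosomal compartment calling.
* The loop caller has no statistical background model; its scores are
  template correlations, not significance values.
* Insulation border prominence (0.1 log2 units) is a heuristic default;
  on shallow maps counting noise can cross it, and on maps with strong
  compartments the plaid transitions themselves are weakly insulating and
  will be called (correctly) as borders.
* Differential-interaction statistics are out of scope: external
  fold-changes or p-values can be injected as score layers and rendered,
  but not computed here.
* `.hic` parsing, tabix/pairix indexing and bigWig export are not
  implemented.
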