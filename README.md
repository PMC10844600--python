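# hicmap

A Python toolkit for chromosome conformation capture (Hi-C / micro-C)
contact matrices: region-queryable binned maps backed by standard file
formats, iterative balancing, distance detrending, structural-feature
annotation (A/B compartments, TAD borders, chromatin loops), interaction
statistics (cis/trans content, P(s), scalograms, virtual 4C, replicate
concordance), map algebra and pileups, static rendering, and a seeded
synthetic-data generator with known ground truth.

It is aimed at genome-organization researchers who want a desk-scale,
scriptable alternative to heavyweight processing pipelines: everything runs
on a laptop, every analysis is a plain function over an in-memory
`ContactMap`, and every number is reproducible from a seed.

## The data model and the statistics it computes

A Hi-C experiment yields pairs of interacting genomic loci.  Binned at a
fixed resolution they form a symmetric sparse matrix of raw counts
`c_ij` over genome bins.  `hicmap` stores the upper triangle only, with
named score layers per record, and ties it to a fixed genome partition
(`BinTable`) carrying per-bin balancing weights and tracks.

* **Balancing (ICE).**  Iterative correction finds per-bin weights `w_i`
  such that the balanced matrix `b_ij = w_i w_j c_ij` has uniform
  marginals, removing any separable (per-bin multiplicative) experimental
  bias; convergence is declared when the variance of mean-scaled marginals
  drops below `tol` (default `1e-5`, at most 200 iterations).
* **Expected / O/E.**  The distance-decay expectation
  `E(d) = sum of b at offset d / number of valid bin pairs at offset d`
  is computed per chromosome; `oe_ij = b_ij / E(d_ij)` removes the
  dominant decay and exposes focal structure.
* **P(s).**  The contact frequency per pairable locus pair on log-spaced
  distance bins, with its log-log slope — the classic readout of polymer
  state.
* **Compartments.**  The leading eigenvector (E1) of the per-chromosome
  O/E correlation matrix, scaled by the square root of its eigenvalue and
  sign-anchored to a phasing track; `E1 > 0` is labeled A, `E1 < 0` B.
* **Insulation / TADs.**  The diamond insulation score
  `IS_i = log2(mean b over the w x w diamond at i / chromosome mean)`;
  borders are IS minima of prominence >= 0.1.
* **Loops.**  Pearson correlation of each local log-O/E patch against a
  central Gaussian-bump template inside a distance band, with non-maximum
  suppression — a deliberately simple single-template detector.
* **Saddle plots.**  Mean O/E between bins grouped into E1 quantiles
  (38 by default), with AA / BB / AB corner summaries and an optional
  minimum-separation filter.
* **SCC.**  Stratum-adjusted correlation between two maps: per-distance
  Pearson correlations combined with `n * sd * sd` weights after light
  mean-filter smoothing — the standard replicate-concordance score.

Supported formats: `.cool` / `.mcool` (HDF5, cooler schema, random access
through the `bin1_offset` index), HiC-Pro matrix + regions text files, 4DN
`.pairs` (plain or gzipped), bedGraph tracks, BED/BEDPE feature lists.
The binary `.hic` format is not parsed; convert to `.cool` first.

## Worked example

```python
import numpy as np
import hicmap as hm
from hicmap.synthetic import SyntheticSpec, synthesize_map

layout = hm.GenomeLayout(("chrI", "chrII"), (400_000, 300_000))
bt = hm.BinTable(layout, 2000)
states = np.where((np.arange(bt.n_bins) // 20) % 2 == 0, 1.0, -1.0)
spec = SyntheticSpec(
    layout, 2000, 500_000, alpha=1.0, cis_fraction=0.9,
    compartment_states=states, plaid_strength=0.4,
    domain_boundaries={"chrI": [100_000, 200_000, 300_000]},
    domain_multiplier=3.0, seed=0,
)
cmap, truth = synthesize_map(spec)
print(repr(cmap))

balanced, result = hm.balance(cmap)
print(f"balanced in {result.n_iterations} iterations, "
      f"marginal variance {result.final_variance:.2e}")

detrended = hm.detrend(balanced)
print(f"genome cis fraction: {hm.cis_trans(cmap).genome_cis_fraction:.3f}")
prof = hm.ps(cmap)
print(f"P(s) log-log slope over 10-100 kb: {prof.fit_slope(10_000, 100_000):.2f}")

comp = hm.call_compartments(detrended, phasing_track=states)
ok = np.isfinite(comp.e1)
agree = 100 * np.mean(np.sign(comp.e1[ok]) == states[ok])
print(f"E1 sign agreement with planted states: {agree:.1f}%")

sad = hm.saddle(detrended, comp.e1, q=8)
print("saddle corner means:", {k: round(v, 2) for k, v in sad.corner_summary.items()})
```

prints

```
<ContactMap genome-wide @ 2000 bp | 47379 records | layers ['count']>
balanced in 14 iterations, marginal variance 6.32e-06
genome cis fraction: 0.900
P(s) log-log slope over 10-100 kb: -1.16
E1 sign agreement with planted states: 100.0%
saddle corner means: {'AA': 1.46, 'BB': 1.51, 'AB': 1.03}
```

The generator planted a decay exponent of 1 (the fitted map-level slope of
−1.16 reflects the short 400 kb chromosomes — fewer pairable loci at large
separations steepen the apparent decay), a 90% cis fraction (recovered
exactly), alternating 40 kb compartment blocks (every bin labeled
correctly) and preferential homotypic contact (AA and BB corner O/E ≈ 1.5
versus AB ≈ 1.0).  Running `hm.insulation(detrended, window=20_000)` on
the same map calls borders at the three planted domain boundaries of chrI
*and* at the plaid block transitions every 40 kb — compartment edges are
themselves weakly insulating, which is worth remembering when interpreting
border calls on real maps.

The same pipeline is available from a shell:

```sh
hicmap synth spec.yml --seed 7 --out-cool raw.cool --out-pairs raw.pairs
hicmap balance raw.cool balanced.cool
hicmap ps balanced.cool ps.tsv
hicmap compartments balanced.cool e1.bedgraph compartments.bed
```

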