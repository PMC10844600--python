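"""Algebra on contact maps, subsampling and snippet aggregation.

``combine`` aligns two maps record-by-record over the union of their
records; ``subsample`` thins counts binomially, which preserves the
distance-dependent contact frequency in expectation; snippet extraction and
aggregation implement pileups (aggregate peak / border analysis) over
structural features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ContactMap, FeatureSet, InteractionSet, Region

__all__ = ["AggregatedMap", "merge", "combine", "subsample", "extract_snippets", "aggregate"]


@dataclass
class AggregatedMap:
    """A stack of equally-sized matrix snippets and their summaries."""

    snippet_stack: np.ndarray  # (k, 2f+1, 2f+1)
    n_contributing: np.ndarray
    score_used: str
    features_used: FeatureSet
    n_dropped: int = 0

    @property
    def mean_slice(self) -> np.ndarray:
        return aggregate(self, "mean")

    @property
    def median_slice(self) -> np.ndarray:
        return aggregate(self, "median")


def _check_compatible(maps) -> None:
    first = maps[0]
    for m in maps[1:]:
        if m.layout != first.layout or m.resolution != first.resolution:
            raise ValueError("maps differ in layout or resolution")


def merge(maps: list[ContactMap]) -> ContactMap:
    """Union of records with raw counts summed; derived layers are dropped."""
    if not maps:
        raise ValueError("nothing to merge")
    _check_compatible(maps)
    n = maps[0].bintable.n_bins
    keys = [m.interactions.bin1_id * n + m.interactions.bin2_id for m in maps]
    counts = [np.asarray(m.interactions.layer("count")) for m in maps]
    allkey = np.concatenate(keys)
    allcnt = np.concatenate(counts)
    uniq, inv = np.unique(allkey, return_inverse=True)
    summed = np.bincount(inv, weights=allcnt, minlength=uniq.size)
    ints = InteractionSet(
        uniq // n, uniq % n, {"count": summed.astype(np.int64)}, canonical=True
    )
    return ContactMap(
        maps[0].bintable.copy(),
        ints,
        focus=maps[0].focus,
        metadata={"merged_from": len(maps)},
    )


def combine(a: ContactMap, b: ContactMap, op: str, score: str = "count") -> ContactMap:
    """Elementwise ``sum``/``subtract``/``divide``/``log2ratio`` of a layer.

    Records are aligned over the union of the two record sets.  An absent
    record contributes 0 to sum/subtract; for divide/log2ratio an absent or
    zero denominator yields NaN (missing), never infinity.
    """
    _check_compatible([a, b])
    if score not in a.layers or score not in b.layers:
        raise KeyError(f"layer {score!r} must be present in both maps")
    n = a.bintable.n_bins
    ka = a.interactions.bin1_id * n + a.interactions.bin2_id
    kb = b.interactions.bin1_id * n + b.interactions.bin2_id
    uniq = np.union1d(ka, kb)

    def _aligned(keys, values, fill):
        out = np.full(uniq.size, fill, dtype=float)
        out[np.searchsorted(uniq, keys)] = values
        return out

    if op in ("sum", "subtract"):
        va = _aligned(ka, np.asarray(a.interactions.layer(score), float), 0.0)
        vb = _aligned(kb, np.asarray(b.interactions.layer(score), float), 0.0)
        combined = va + vb if op == "sum" else va - vb
    elif op in ("divide", "log2ratio"):
        va = _aligned(ka, np.asarray(a.interactions.layer(score), float), np.nan)
        vb = _aligned(kb, np.asarray(b.interactions.layer(score), float), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(np.isfinite(vb) & (vb != 0), va / vb, np.nan)
            combined = np.log2(ratio) if op == "log2ratio" else ratio
    else:
        raise ValueError("op must be sum, subtract, divide or log2ratio")
    ca = _aligned(ka, np.asarray(a.interactions.layer("count"), float), 0.0)
    cb = _aligned(kb, np.asarray(b.interactions.layer("count"), float), 0.0)
    ints = InteractionSet(
        uniq // n,
        uniq % n,
        {"count": (ca + cb).astype(np.int64), "combined": combined},
        canonical=True,
    )
    return ContactMap(
        a.bintable.copy(), ints, focus=a.focus, metadata={"combined_op": op}
    )


def subsample(
    cmap: ContactMap,
    fraction: float | None = None,
    target_count: int | None = None,
    seed: int = 0,
) -> ContactMap:
    """Binomially thin raw counts to a fraction or a target total.

    Each record's count is replaced by Binomial(count, p) with a shared p,
    which preserves the sample's distance-dependent interaction frequency
    in expectation.  Zero records are dropped.  Reproducible for a seed.
    """
    if (fraction is None) == (target_count is None):
        raise ValueError("give exactly one of fraction or target_count")
    counts = np.rint(np.asarray(cmap.interactions.layer("count"))).astype(np.int64)
    total = int(counts.sum())
    if fraction is None:
        if target_count > total:
            raise ValueError(f"target {target_count} exceeds total {total}")
        p = target_count / total
    else:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        p = float(fraction)
    if p == 1.0:
        return cmap._shallow()
    rng = np.random.default_rng(seed)
    new = rng.binomial(counts, p)
    keep = new > 0
    ints = InteractionSet(
        cmap.interactions.bin1_id[keep],
        cmap.interactions.bin2_id[keep],
        {"count": new[keep]},
        canonical=True,
    )
    return ContactMap(
        cmap.bintable.copy(),
        ints,
        focus=cmap.focus,
        metadata={"subsampled_p": p, "seed": seed},
    )


def extract_snippets(
    cmap: ContactMap,
    features: FeatureSet,
    flank: int,
    score: str = "oe",
    max_invalid_fraction: float = 0.5,
) -> AggregatedMap:
    """Cut (2f+1)x(2f+1) windows of the chosen layer around features.

    Border-like features give on-diagonal windows centered at the feature
    midpoint bin; loops give off-diagonal windows centered at the anchor
    pair.  Windows crossing a chromosome end, or with more than
    ``max_invalid_fraction`` missing pixels, are dropped (never padded) and
    tallied.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    bt = cmap.bintable
    if flank % bt.resolution != 0:
        raise ValueError("flank must be a multiple of the resolution")
    f = flank // bt.resolution
    dense_cache: dict[str, np.ndarray] = {}

    def chrom_dense(chrom: str) -> np.ndarray:
        if chrom not in dense_cache:
            sub = cmap._shallow(focus=Region(chrom, 0, cmap.layout.length(chrom)))
            d = sub.dense(score)
            if bt.weights is not None:
                bad = ~np.isfinite(bt.weights[bt.chrom_slice(chrom)])
                d[bad, :] = np.nan
                d[:, bad] = np.nan
            return dense_cache.setdefault(chrom, d)
        return dense_cache[chrom]

    snippets = []
    kept_idx = []
    n_dropped = 0
    for idx in range(len(features)):
        r1 = features.regions[idx]
        if features.kind == "loop":
            r2 = features.regions2[idx]
            if r1.chrom != r2.chrom:
                n_dropped += 1
                continue
        else:
            r2 = r1
        sl = bt.chrom_slice(r1.chrom)
        nloc = sl.stop - sl.start
        ci = (r1.start + r1.end) // 2 // bt.resolution
        cj = (r2.start + r2.end) // 2 // bt.resolution
        if ci - f < 0 or cj - f < 0 or ci + f >= nloc or cj + f >= nloc:
            n_dropped += 1
            continue
        d = chrom_dense(r1.chrom)
        snip = d[ci - f : ci + f + 1, cj - f : cj + f + 1].astype(float)
        if np.mean(~np.isfinite(snip)) > max_invalid_fraction:
            n_dropped += 1
            continue
        snippets.append(snip)
        kept_idx.append(idx)
    if not snippets:
        raise ValueError("all snippets were dropped (out of bounds or invalid)")
    stack = np.stack(snippets)
    kept = FeatureSet(
        features.kind,
        [features.regions[i] for i in kept_idx],
        features.scores[kept_idx],
        labels=[features.labels[i] for i in kept_idx] if features.labels else None,
        regions2=[features.regions2[i] for i in kept_idx] if features.regions2 else None,
    )
    n_contrib = np.isfinite(stack).sum(axis=0)
    return AggregatedMap(stack, n_contrib, score, kept, n_dropped)


def aggregate(agg: AggregatedMap, stat: str = "mean") -> np.ndarray:
    """Per-pixel mean or median over non-missing snippet contributions."""
    if agg.snippet_stack.shape[0] == 0:
        raise ValueError("empty snippet stack")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "mean":
            return np.nanmean(agg.snippet_stack, axis=0)
        if stat == "median":
            return np.nanmedian(agg.snippet_stack, axis=0)
    raise ValueError("stat must be mean or median")
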