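"""Matrix balancing, expected-signal estimation, O/E detrending and
correlation maps.

Balancing follows the iterative-correction (ICE) scheme: per-bin weights
w_i are updated until every valid bin's balanced marginal
``m_i = sum_j w_i w_j c_ij`` is uniform, which removes any separable
(per-bin multiplicative) experimental bias.  Weights are rescaled on
convergence so the mean balanced marginal equals 1.  Bins flagged by the
MAD-max coverage filter carry a NaN weight and are excluded from every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ContactMap

__all__ = [
    "BalanceResult",
    "ExpectedProfile",
    "filter_bins",
    "balance",
    "expected",
    "detrend",
    "correlate",
]


@dataclass
class BalanceResult:
    weights: np.ndarray
    n_iterations: int
    converged: bool
    final_variance: float


@dataclass
class ExpectedProfile:
    """Distance-decay expectation per chromosome plus trans expectations.

    ``cis[chrom]`` maps to ``(E, n_pairs)`` where ``E[d]`` is the mean score
    over valid bin pairs at bin-offset d (absent records count as 0) and
    ``n_pairs[d]`` the number of valid pairs at that offset.  ``trans`` maps
    chromosome pairs to ``(mean, n_pairs)``.
    """

    resolution: int
    cis: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    trans: dict[tuple[str, str], tuple[float, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (E, n) in self.cis.items():
            for d in range(E.size):
                rows.append((chrom, d * self.resolution, int(n[d]), E[d]))
        return pd.DataFrame(rows, columns=["chrom", "offset_bp", "n_pairs", "expected"])


def _marginals(cmap: ContactMap, values: np.ndarray) -> np.ndarray:
    """Row sums of the full symmetric matrix, diagonal counted once."""
    n = cmap.bintable.n_bins
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    m = np.bincount(b1, weights=values, minlength=n) + np.bincount(
        b2, weights=values, minlength=n
    )
    diag = b1 == b2
    if diag.any():
        m -= np.bincount(b1[diag], weights=values[diag], minlength=n)
    return m


def filter_bins(cmap: ContactMap, mad_max: float = 5.0) -> ContactMap:
    """Flag low-coverage bins with a NaN weight (MAD-max filter).

    A bin is filtered when its raw marginal is zero, or when its log10
    marginal falls more than ``mad_max`` robust standard deviations
    (1.4826 x the median absolute deviation, the Gaussian-consistent MAD
    scaling) below the per-chromosome median of nonzero-bin log marginals.
    The scaling keeps genuine coverage structure (e.g. insulated domain
    boundaries) while catching unmappable or artefactual bins.
    """
    out = cmap.copy()
    counts = np.asarray(out.interactions.layer("count"), dtype=float)
    marg = _marginals(out, counts)
    weights = np.ones(out.bintable.n_bins)
    weights[marg == 0] = np.nan
    for chrom in out.layout.names:
        sl = out.bintable.chrom_slice(chrom)
        m = marg[sl]
        nz = m > 0
        if nz.sum() < 3:
            continue
        logm = np.log10(m[nz])
        med = np.median(logm)
        mad = 1.4826 * np.median(np.abs(logm - med))
        if mad == 0:
            continue
        bad = np.zeros(m.size, dtype=bool)
        bad[nz] = logm < med - mad_max * mad
        weights[sl][bad] = np.nan
    out.bintable.weights = weights
    out.metadata["n_bins_filtered"] = int(np.isnan(weights).sum())
    return out


def balance(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    mad_max: float = 5.0,
    cis_only: bool = False,
) -> tuple[ContactMap, BalanceResult]:
    """Iteratively correct the map so valid-bin marginals are uniform.

    Runs genome-wide (cis + trans) by default; ``cis_only`` restricts the
    correction to intra-chromosomal records.  Returns the map with a
    ``balanced`` layer and weights on its bin table, plus a convergence
    report.  Non-convergence is flagged, not raised.
    """
    if cmap.bintable.weights is None or cmap.metadata.get("n_bins_filtered") is None:
        cmap = filter_bins(cmap, mad_max=mad_max)
    else:
        cmap = cmap.copy()
    counts = np.asarray(cmap.interactions.layer("count"), dtype=float)
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    if cis_only:
        same = cmap.bintable.chrom_id[b1] == cmap.bintable.chrom_id[b2]
        counts = np.where(same, counts, 0.0)
    w = cmap.bintable.weights.copy()
    valid = np.isfinite(w)
    w[valid] = 1.0
    var = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        bal = w[b1] * w[b2] * counts
        bal = np.nan_to_num(bal)
        m = _marginals(cmap, bal)
        mv = m[valid]
        mean = mv.mean()
        if mean == 0:
            break
        var = float(np.var(mv / mean))
        if var < tol:
            converged = True
            break
        scale = np.ones_like(w)
        scale[valid] = mv / mean
        w = w / scale
    # rescale so the mean balanced marginal over valid bins equals 1
    bal = np.nan_to_num(w[b1] * w[b2] * counts)
    mean_marg = _marginals(cmap, bal)[valid].mean()
    if mean_marg > 0:
        w *= 1.0 / np.sqrt(mean_marg)
    full_counts = np.asarray(cmap.interactions.layer("count"), dtype=float)
    balanced = w[b1] * w[b2] * full_counts
    out = cmap._shallow(interactions=cmap.interactions.with_layer("balanced", balanced))
    out.bintable.weights = w
    out.metadata["balanced"] = {"converged": converged, "n_iterations": n_iter,
                                "variance": var, "cis_only": cis_only}
    result = BalanceResult(w, n_iter, converged, var)
    return out, result


def _valid_pair_counts(valid: np.ndarray) -> np.ndarray:
    """Number of valid bin pairs at each offset d (d=0..n-1) within a chrom."""
    n = valid.size
    out = np.empty(n, dtype=np.int64)
    out[0] = int(valid.sum())
    for d in range(1, n):
        out[d] = int(np.count_nonzero(valid[:-d] & valid[d:]))
    return out


def expected(cmap: ContactMap, score: str = "balanced") -> ExpectedProfile:
    """Per-chromosome mean score at each bin offset, plus trans means.

    Valid bin pairs with no record contribute 0, so
    ``sum_d n_pairs[d] * E[d]`` conserves the total score mass.
    """
    values = np.asarray(cmap.interactions.layer(score), dtype=float)
    bt = cmap.bintable
    if bt.weights is None:
        raise ValueError("filter/balance the map before computing expected")
    valid = np.isfinite(bt.weights)
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    c1, c2 = bt.chrom_id[b1], bt.chrom_id[b2]
    prof = ExpectedProfile(resolution=bt.resolution)
    vals = np.nan_to_num(values)
    pair_ok = valid[b1] & valid[b2]
    for ci, chrom in enumerate(cmap.layout.names):
        sl = bt.chrom_slice(chrom)
        v = valid[sl]
        n = sl.stop - sl.start
        if n == 0:
            continue
        mask = (c1 == ci) & (c2 == ci) & pair_ok
        d = b2[mask] - b1[mask]
        sums = np.bincount(d, weights=vals[mask], minlength=n)
        n_pairs = _valid_pair_counts(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            E = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
        prof.cis[chrom] = (E, n_pairs)
    n_valid = np.array(
        [int(valid[bt.chrom_slice(c)].sum()) for c in cmap.layout.names]
    )
    for i, ci in enumerate(cmap.layout.names):
        for j in range(i + 1, cmap.layout.n_chroms):
            cj = cmap.layout.names[j]
            mask = (c1 == i) & (c2 == j) & pair_ok
            npairs = int(n_valid[i] * n_valid[j])
            mean = float(vals[mask].sum() / npairs) if npairs else np.nan
            prof.trans[(ci, cj)] = (mean, npairs)
    return prof


def detrend(cmap: ContactMap, score: str = "balanced") -> ContactMap:
    """Attach ``expected`` and ``oe`` (= score / expected) layers.

    Cis records use the per-chromosome distance decay, trans records the
    chromosome-pair mean; records whose expectation is 0 get NaN.
    """
    if score not in cmap.layers:
        cmap, _ = balance(cmap)
    prof = expected(cmap, score)
    bt = cmap.bintable
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    c1, c2 = bt.chrom_id[b1], bt.chrom_id[b2]
    exp = np.full(len(cmap.interactions), np.nan)
    for ci, chrom in enumerate(cmap.layout.names):
        mask = (c1 == ci) & (c2 == ci)
        if mask.any():
            E, _ = prof.cis[chrom]
            exp[mask] = E[b2[mask] - b1[mask]]
    for (ci, cj), (mean, _) in prof.trans.items():
        i, j = cmap.layout.index(ci), cmap.layout.index(cj)
        mask = (c1 == i) & (c2 == j)
        if mask.any():
            exp[mask] = mean
    values = np.asarray(cmap.interactions.layer(score), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, values / exp, np.nan)
    ints = cmap.interactions.with_layer("expected", exp).with_layer("oe", oe)
    return cmap._shallow(interactions=ints)


def correlate(
    cmap: ContactMap, per_chromosome: bool = True, min_shared: int = 3
) -> "np.ndarray | dict[str, np.ndarray]":
    """Pearson correlation of O/E interaction profiles (the plaid map).

    Entry (i, j) correlates rows i and j of the dense O/E matrix over
    positions valid in both (pairwise-complete, at least ``min_shared``
    shared positions).  The main diagonal of the O/E input (d = 0) is
    excluded to avoid self-inflation; filtered bins yield NaN rows.
    """
    if "oe" not in cmap.layers:
        cmap = detrend(cmap)
    if per_chromosome:
        out = {}
        for chrom in cmap.layout.names:
            out[chrom] = _corr_block(cmap, chrom, min_shared)
        return out
    raise NotImplementedError("genome-wide correlation matrix is per-chromosome only")


def _corr_block(cmap: ContactMap, chrom: str, min_shared: int) -> np.ndarray:
    bt = cmap.bintable
    sl = bt.chrom_slice(chrom)
    n = sl.stop - sl.start
    valid = np.isfinite(bt.weights[sl]) if bt.weights is not None else np.ones(n, bool)
    from .model import Region

    sub = cmap._shallow(focus=Region(chrom, 0, cmap.layout.length(chrom)))
    oe = sub.dense("oe")
    # absent records between two valid bins are true zeros of the O/E field
    vv = np.outer(valid, valid)
    oe[vv & ~np.isfinite(oe)] = 0.0
    oe[~vv] = np.nan
    np.fill_diagonal(oe, np.nan)  # d = 0 excluded
    if valid.sum() < min_shared or n < 3:
        return np.full((n, n), np.nan)
    masked = np.ma.masked_invalid(oe)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(masked).filled(np.nan)
    shared = (~masked.mask).astype(int) @ (~masked.mask).astype(int).T
    corr[shared < min_shared] = np.nan
    corr[~vv] = np.nan
    idx = np.where(valid)[0]
    corr[idx, idx] = 1.0
    return corr
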