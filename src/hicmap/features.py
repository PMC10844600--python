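"""Structural-feature annotation.

* A/B compartments: leading eigenvector of the per-chromosome O/E
  correlation matrix, scaled by sqrt(|eigenvalue|), sign-anchored to a
  phasing track (e.g. GC content or gene density) when one is given.
* TAD borders: diamond insulation score (log2 of the mean balanced signal
  in a w x w diamond sliding along the diagonal, relative to the
  chromosome mean), with borders at local minima of sufficient prominence.
* Chromatin loops: a deliberately simple single-template detector that
  correlates each log-O/E patch in a distance band against a central
  Gaussian bump, with non-maximum suppression.
* Saddle summaries: mean O/E between bins grouped into E1 quantiles, with
  an optional minimum-separation filter, plus AA/BB/AB corner means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .balance import correlate, detrend
from .model import ContactMap, FeatureSet, Region

__all__ = [
    "CompartmentResult",
    "InsulationResult",
    "SaddleData",
    "call_compartments",
    "insulation",
    "call_loops",
    "saddle",
]


@dataclass
class CompartmentResult:
    e1: np.ndarray  # per-bin, scaled by sqrt(|eigenvalue|)
    labels: np.ndarray  # "A"/"B"/"" per bin
    eigenvalue: dict[str, float]
    phased: bool

    def compartments(self, cmap: ContactMap) -> FeatureSet:
        """Merge consecutive same-label bins into compartment features."""
        bt = cmap.bintable
        regions, scores, labels = [], [], []
        names = cmap.layout.names
        for chrom in names:
            sl = bt.chrom_slice(chrom)
            lab = self.labels[sl]
            e1 = self.e1[sl]
            i = 0
            while i < lab.size:
                if lab[i] == "":
                    i += 1
                    continue
                j = i
                while j + 1 < lab.size and lab[j + 1] == lab[i]:
                    j += 1
                regions.append(
                    Region(chrom, int(bt.start[sl][i]), int(bt.end[sl][j]))
                )
                scores.append(float(np.nanmean(e1[i : j + 1])))
                labels.append(lab[i])
                i = j + 1
        return FeatureSet("compartment", regions, np.array(scores), labels=labels)


@dataclass
class InsulationResult:
    is_track: np.ndarray  # log2 insulation score per bin
    window: int
    borders: FeatureSet


@dataclass
class SaddleData:
    q: int
    group_bounds: np.ndarray
    s_matrix: np.ndarray
    counts: np.ndarray
    corner_summary: dict[str, float] = field(default_factory=dict)


def _power_leading_eigvec(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenpair of a symmetric matrix (largest eigenvalue)."""
    vals, vecs = np.linalg.eigh(mat)
    return vecs[:, -1], float(vals[-1])


def call_compartments(
    cmap: ContactMap, phasing_track: np.ndarray | None = None, min_bins: int = 10
) -> CompartmentResult:
    """A/B compartment eigenvector per chromosome.

    Operates on the O/E correlation matrix (the plaid pattern); the first
    eigenvector is scaled by sqrt(|lambda_1|) and its sign per chromosome
    is flipped so its correlation with the phasing track is positive.
    Without a phasing track the sign is arbitrary (``phased=False``).
    """
    if "oe" not in cmap.layers:
        cmap = detrend(cmap)
    corr = correlate(cmap)
    bt = cmap.bintable
    e1 = np.full(bt.n_bins, np.nan)
    eigenvalue: dict[str, float] = {}
    for chrom in cmap.layout.names:
        sl = bt.chrom_slice(chrom)
        block = corr[chrom]
        valid = np.where(np.isfinite(np.diagonal(block)))[0]
        if valid.size < min_bins:
            continue
        sub = block[np.ix_(valid, valid)]
        sub = np.nan_to_num(sub)
        vec, lam = _power_leading_eigvec(sub)
        e1[sl.start + valid] = vec * np.sqrt(abs(lam))
        eigenvalue[chrom] = lam
    phased = False
    if phasing_track is not None:
        phasing_track = np.asarray(phasing_track, dtype=float)
        for chrom in eigenvalue:
            sl = bt.chrom_slice(chrom)
            x, y = e1[sl], phasing_track[sl]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                if r < 0:
                    e1[sl] = -e1[sl]
        phased = True
    else:
        warnings.warn(
            "no phasing track given: compartment eigenvector signs are arbitrary",
            stacklevel=2,
        )
    labels = np.where(e1 > 0, "A", np.where(e1 < 0, "B", ""))
    labels[~np.isfinite(e1)] = ""
    bt.set_track("E1", e1)
    return CompartmentResult(e1, labels, eigenvalue, phased)


def insulation(
    cmap: ContactMap,
    window: int,
    prominence: float = 0.1,
    min_valid_fraction: float = 0.5,
    score: str = "balanced",
) -> InsulationResult:
    """Diamond insulation score and border calls.

    For bin i, the raw score is the mean of the chosen layer over the
    w x w diamond upstream-x-downstream of i (the bin's own row/column is
    excluded); IS_i = log2(raw_i / chromosome mean of raw).  The score is
    only defined where the full diamond fits inside the chromosome and at
    least ``min_valid_fraction`` of its pixels are valid.  Borders are
    local minima of IS with at least the requested prominence (log2 units).
    """
    bt = cmap.bintable
    if window % bt.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // bt.resolution
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    if score not in cmap.layers:
        raise KeyError(f"layer {score!r} not present (balance the map first)")
    is_track = np.full(bt.n_bins, np.nan)
    regions, proms = [], []
    for chrom in cmap.layout.names:
        sl = bt.chrom_slice(chrom)
        n = sl.stop - sl.start
        dense = cmap._shallow(
            focus=Region(chrom, 0, cmap.layout.length(chrom))
        ).dense(score)
        if bt.weights is not None:
            bad = ~np.isfinite(bt.weights[sl])
            dense[bad, :] = np.nan
            dense[:, bad] = np.nan
        # absent records between valid bins are zeros of the balanced field
        if bt.weights is not None:
            vv = np.outer(~bad, ~bad)
            dense[vv & ~np.isfinite(dense)] = 0.0
        else:
            dense = np.nan_to_num(dense)
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            diamond = dense[i - w : i, i + 1 : i + w + 1]
            finite = np.isfinite(diamond)
            if finite.mean() < min_valid_fraction:
                continue
            raw[i] = diamond[finite].mean()
        ok = np.isfinite(raw)
        if not ok.any() or raw[ok].max() <= 0:
            continue
        pos = raw[ok & (raw > 0)] if (ok & (raw > 0)).any() else None
        # an all-zero diamond is a maximally insulating junction: floor it at
        # half the smallest positive diamond mean so its log score is defined
        floor = 0.5 * pos.min()
        mean_raw = raw[ok].mean()
        chrom_is = np.full(n, np.nan)
        chrom_is[ok] = np.log2(np.maximum(raw[ok], floor) / mean_raw)
        is_track[sl] = chrom_is
        # border calls on contiguous defined segments
        idx = np.where(np.isfinite(chrom_is))[0]
        if idx.size == 0:
            continue
        splits = np.where(np.diff(idx) > 1)[0]
        for seg in np.split(idx, splits + 1):
            if seg.size < 3:
                continue
            seg_is = chrom_is[seg]
            peaks, props = _signal.find_peaks(-seg_is, prominence=prominence)
            for p, prom in zip(peaks, props["prominences"]):
                b = sl.start + seg[p]
                regions.append(
                    Region(chrom, int(bt.start[b]), int(bt.end[b]))
                )
                proms.append(float(prom))
    borders = FeatureSet("border", regions, np.array(proms, dtype=float))
    bt.set_track("insulation", is_track)
    return InsulationResult(is_track, window, borders)


def _loop_template(k: int, sigma: float = 1.0) -> np.ndarray:
    ax = np.arange(-k, k + 1)
    xx, yy = np.meshgrid(ax, ax)
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def call_loops(
    cmap: ContactMap,
    band: tuple[float, float],
    kernel_halfwidth: int = 3,
    rho_min: float = 0.35,
    min_separation: int = 2,
) -> FeatureSet:
    """Detect focal contact enrichments (loops) in a cis distance band.

    Each pixel's local log-O/E patch is correlated against a fixed central
    Gaussian-bump template; candidates need correlation >= rho_min and
    O/E > 1 at the center, and are pruned by non-maximum suppression
    within ``min_separation`` bins (Chebyshev distance).
    """
    if "oe" not in cmap.layers:
        cmap = detrend(cmap)
    bt = cmap.bintable
    res = bt.resolution
    d_lo = max(1, int(band[0] // res))
    d_hi = int(band[1] // res)
    if d_hi < d_lo:
        raise ValueError("empty distance band")
    k = kernel_halfwidth
    template = _loop_template(k)
    t = template - template.mean()
    t_norm = np.sqrt((t**2).sum())
    out_regions1, out_regions2, out_scores = [], [], []
    for chrom in cmap.layout.names:
        sl = bt.chrom_slice(chrom)
        n = sl.stop - sl.start
        dense = cmap._shallow(
            focus=Region(chrom, 0, cmap.layout.length(chrom))
        ).dense("oe")
        if bt.weights is not None:
            bad = ~np.isfinite(bt.weights[sl])
            dense[bad, :] = np.nan
            dense[:, bad] = np.nan
            vv = np.outer(~bad, ~bad)
            dense[vv & ~np.isfinite(dense)] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logoe = np.log2(np.maximum(dense, 1e-6))
        logoe[~np.isfinite(dense)] = np.nan
        cands = []
        for i in range(k, n - k):
            j_lo = max(i + d_lo, k)
            j_hi = min(i + d_hi, n - k - 1)
            for j in range(j_lo, j_hi + 1):
                if not (np.isfinite(dense[i, j]) and dense[i, j] > 1):
                    continue
                patch = logoe[i - k : i + k + 1, j - k : j + k + 1]
                if not np.isfinite(patch).all():
                    continue
                pc = patch - patch.mean()
                denom = np.sqrt((pc**2).sum()) * t_norm
                if denom == 0:
                    continue
                rho = float((pc * t).sum() / denom)
                if rho >= rho_min:
                    cands.append((rho, i, j))
        # non-maximum suppression, strongest first
        cands.sort(reverse=True)
        kept: list[tuple[int, int]] = []
        for rho, i, j in cands:
            if any(
                max(abs(i - pi), abs(j - pj)) <= min_separation for pi, pj in kept
            ):
                continue
            kept.append((i, j))
            out_regions1.append(
                Region(chrom, int(bt.start[sl.start + i]), int(bt.end[sl.start + i]))
            )
            out_regions2.append(
                Region(chrom, int(bt.start[sl.start + j]), int(bt.end[sl.start + j]))
            )
            out_scores.append(rho)
    return FeatureSet(
        "loop", out_regions1, np.array(out_scores, dtype=float), regions2=out_regions2
    )


def saddle(
    cmap: ContactMap,
    e1: np.ndarray,
    q: int = 38,
    min_s: float = 0,
    include_trans: bool = False,
) -> SaddleData:
    """Mean O/E between bins grouped into E1 quantiles (saddle plot data).

    Valid bins are split into ``q`` equal-count groups ordered from the
    strongest B (lowest E1) to the strongest A (highest E1); entry (a, b)
    of the symmetric matrix is the mean O/E over records joining the two
    groups, restricted to cis pairs at least ``min_s`` apart (trans pairs
    excluded unless requested).  Corner means over the A/B sign classes
    are reported alongside, mirroring compartment-strength summaries.
    """
    if "oe" not in cmap.layers:
        cmap = detrend(cmap)
    e1 = np.asarray(e1, dtype=float)
    bt = cmap.bintable
    valid = np.isfinite(e1)
    if bt.weights is not None:
        valid &= np.isfinite(bt.weights)
    if valid.sum() < q:
        raise ValueError(f"only {int(valid.sum())} valid bins for {q} groups")
    ranks = np.full(bt.n_bins, -1, dtype=int)
    vals = e1[valid]
    order = np.argsort(vals, kind="stable")
    groups = np.floor(np.arange(vals.size) * q / vals.size).astype(int)
    gg = np.empty(vals.size, dtype=int)
    gg[order] = groups
    ranks[valid] = gg
    bounds = np.quantile(vals, np.linspace(0, 1, q + 1))
    ints = cmap.interactions
    oe = np.asarray(ints.layer("oe"), dtype=float)
    b1, b2 = ints.bin1_id, ints.bin2_id
    cis = bt.chrom_id[b1] == bt.chrom_id[b2]
    sep_ok = np.abs(bt.start[b2] - bt.start[b1]) >= min_s
    mask = np.isfinite(oe) & (ranks[b1] >= 0) & (ranks[b2] >= 0)
    mask &= (cis & sep_ok) if not include_trans else ((cis & sep_ok) | ~cis)
    g1, g2, v = ranks[b1[mask]], ranks[b2[mask]], oe[mask]
    s_sum = np.zeros((q, q))
    s_cnt = np.zeros((q, q), dtype=np.int64)
    np.add.at(s_sum, (g1, g2), v)
    np.add.at(s_cnt, (g1, g2), 1)
    s_sum = s_sum + s_sum.T - np.diag(np.diagonal(s_sum))
    s_cnt = s_cnt + s_cnt.T - np.diag(np.diagonal(s_cnt))
    with np.errstate(invalid="ignore"):
        s_matrix = np.where(s_cnt > 0, s_sum / np.maximum(s_cnt, 1), np.nan)
    sign1 = np.sign(e1[b1[mask]])
    sign2 = np.sign(e1[b2[mask]])
    corner = {}
    for name, sel in (
        ("AA", (sign1 > 0) & (sign2 > 0)),
        ("BB", (sign1 < 0) & (sign2 < 0)),
        ("AB", sign1 * sign2 < 0),
    ):
        corner[name] = float(np.mean(v[sel])) if sel.any() else np.nan
    return SaddleData(q, bounds, s_matrix, s_cnt, corner)
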