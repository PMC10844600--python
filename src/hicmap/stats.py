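"""Interaction-centric statistics.

* cis/trans content per chromosome (chromosome territoriality),
* the distance-dependent contact frequency P(s) and its log-log slope,
* scalograms (per-bin quantiles of the contact-distance distribution),
* virtual 4C viewpoint profiles,
* stratum-adjusted correlation coefficients (SCC) for replicate
  concordance, computed per chromosome on smoothed dense cis matrices and
  combined with n * sd * sd stratum weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import ContactMap, Region, parse_region
from .io import PairsTable

__all__ = [
    "PsProfile",
    "CisTransTable",
    "SccResult",
    "cis_trans",
    "ps",
    "scalogram",
    "virtual_4c",
    "scc",
]


@dataclass
class PsProfile:
    """P(s) over log-spaced distance bins plus its smoothed slope."""

    bin_edges: np.ndarray
    s_mid: np.ndarray
    p: np.ndarray
    slope: np.ndarray
    n_contacts: np.ndarray
    n_possible: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_lo": self.bin_edges[:-1],
                "s_hi": self.bin_edges[1:],
                "s_mid": self.s_mid,
                "p": self.p,
                "slope": self.slope,
                "n_contacts": self.n_contacts,
            }
        )

    def fit_slope(self, s_lo: float | None = None, s_hi: float | None = None) -> float:
        """Least-squares log-log slope over a distance range."""
        ok = (self.p > 0) & np.isfinite(self.p)
        if s_lo is not None:
            ok &= self.s_mid >= s_lo
        if s_hi is not None:
            ok &= self.s_mid <= s_hi
        x, y = np.log10(self.s_mid[ok]), np.log10(self.p[ok])
        return float(np.polyfit(x, y, 1)[0])


@dataclass
class CisTransTable:
    table: pd.DataFrame  # chrom, n_cis, n_trans, cis_fraction

    @property
    def genome_cis_fraction(self) -> float:
        n_cis = self.table["n_cis"].sum()
        # each trans contact was attributed to both partner chromosomes
        n_trans = self.table["n_trans"].sum() / 2
        return float(n_cis / (n_cis + n_trans)) if n_cis + n_trans else np.nan


@dataclass
class SccResult:
    scc: float
    per_stratum: pd.DataFrame  # stratum, rho, weight, n
    per_chromosome: dict[str, float] = field(default_factory=dict)


def cis_trans(cmap: ContactMap) -> CisTransTable:
    """Per-chromosome cis/trans contact tallies from raw counts.

    A trans contact is attributed to both partner chromosomes.
    """
    counts = np.asarray(cmap.interactions.layer("count"), dtype=float)
    bt = cmap.bintable
    c1 = bt.chrom_id[cmap.interactions.bin1_id]
    c2 = bt.chrom_id[cmap.interactions.bin2_id]
    n = cmap.layout.n_chroms
    same = c1 == c2
    n_cis = np.bincount(c1[same], weights=counts[same], minlength=n)
    n_trans = np.bincount(c1[~same], weights=counts[~same], minlength=n) + np.bincount(
        c2[~same], weights=counts[~same], minlength=n
    )
    tot = n_cis + n_trans
    with np.errstate(invalid="ignore"):
        frac = np.where(tot > 0, n_cis / np.maximum(tot, 1), np.nan)
    df = pd.DataFrame(
        {
            "chrom": cmap.layout.names,
            "n_cis": n_cis.astype(np.int64),
            "n_trans": n_trans.astype(np.int64),
            "cis_fraction": frac,
        }
    )
    return CisTransTable(df)


def _log_edges(min_s: float, max_s: float, ratio: float) -> np.ndarray:
    if not (ratio > 1 and 0 < min_s < max_s):
        raise ValueError("need ratio > 1 and 0 < min_s < max_s")
    n = int(np.ceil(np.log(max_s / min_s) / np.log(ratio)))
    return min_s * ratio ** np.arange(n + 1)


def _pairable_loci(layout, edges: np.ndarray, unit: float) -> np.ndarray:
    """Number of pairable locus pairs per distance bin, in units of ``unit``.

    For a chromosome of length L there are (L - s)/unit pairs at distance s;
    integrating over each bin and summing over chromosomes makes P(s) a
    per-pair density comparable across genomes.
    """
    out = np.zeros(edges.size - 1)
    for _, L in layout.items():
        lo = np.minimum(edges[:-1], L)
        hi = np.minimum(edges[1:], L)
        width = np.maximum(hi - lo, 0)
        s_mid = (lo + hi) / 2
        out += np.maximum(L - s_mid, 0) * width / unit**2
    return out


def _pairable_bins_discrete(layout, edges: np.ndarray, resolution: int) -> np.ndarray:
    """Discrete bin-pair counts per distance bin for binned maps.

    At bin offset d a chromosome with n bins has n - d pairs; summing the
    offsets whose genomic separation d*resolution falls in each log bin
    keeps single-offset bins exact and leaves truly empty bins at zero.
    """
    out = np.zeros(edges.size - 1)
    for _, L in layout.items():
        n = -(-L // resolution)
        d = np.arange(1, n)
        s = d.astype(float) * resolution
        which = np.searchsorted(edges, s, side="right") - 1
        ok = (which >= 0) & (which < out.size) & (s >= edges[0]) & (s < edges[-1])
        np.add.at(out, which[ok], (n - d[ok]).astype(float))
    return out


def _rolling_mean(v: np.ndarray, window: int = 3) -> np.ndarray:
    out = np.full_like(v, np.nan, dtype=float)
    for i in range(v.size):
        lo, hi = max(0, i - window // 2), min(v.size, i + window // 2 + 1)
        seg = v[lo:hi]
        if np.isfinite(seg).any():
            out[i] = np.nanmean(seg)
    return out


def _slope(s_mid: np.ndarray, p: np.ndarray, window: int = 3) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log10(p), np.nan)
    logp = _rolling_mean(logp, window)
    logs = np.log10(s_mid)
    slope = np.full_like(logp, np.nan)
    for i in range(1, logp.size - 1):
        if np.isfinite(logp[i - 1]) and np.isfinite(logp[i + 1]):
            slope[i] = (logp[i + 1] - logp[i - 1]) / (logs[i + 1] - logs[i - 1])
    return slope


def ps(
    source: "PairsTable | ContactMap",
    ratio: float = 1.1,
    min_s: float | None = None,
    max_s: float | None = None,
) -> PsProfile:
    """Distance-dependent contact frequency P(s) on log-spaced bins.

    P(s) is the number of cis contacts per distance bin divided by (total
    cis contacts x pairable locus pairs in that bin), i.e. a per-pair
    density; chromosomes of different lengths are therefore comparable.
    The slope is a centered finite difference of log10 P against log10 s
    after rolling-mean smoothing (window 3).
    """
    if isinstance(source, PairsTable):
        s = source.cis_distances().astype(float)
        layout = source.layout
        unit = 1.0
        weights = None
        default_min = 100.0
    else:
        ints = source.interactions
        bt = source.bintable
        same = bt.chrom_id[ints.bin1_id] == bt.chrom_id[ints.bin2_id]
        d = (ints.bin2_id - ints.bin1_id)[same]
        s = d.astype(float) * bt.resolution
        weights = np.asarray(ints.layer("count"), dtype=float)[same]
        keep = d > 0
        s, weights = s[keep], weights[keep]
        layout = source.layout
        unit = float(bt.resolution)
        default_min = float(bt.resolution)
    if s.size == 0:
        raise ValueError("no cis contacts")
    if min_s is None:
        min_s = default_min
    if max_s is None:
        max_s = float(max(layout.lengths))
    edges = _log_edges(min_s, max_s, ratio)
    inside = (s >= edges[0]) & (s < edges[-1])
    n_contacts = np.histogram(
        s[inside], bins=edges, weights=None if weights is None else weights[inside]
    )[0].astype(float)
    total = n_contacts.sum()
    if total == 0:
        raise ValueError("no cis contacts in the requested distance range")
    if isinstance(source, PairsTable):
        n_possible = _pairable_loci(layout, edges, unit)
    else:
        n_possible = _pairable_bins_discrete(layout, edges, source.resolution)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_possible > 0, n_contacts / (total * n_possible), np.nan)
    s_mid = np.sqrt(edges[:-1] * edges[1:])
    return PsProfile(edges, s_mid, p, _slope(s_mid, p), n_contacts, n_possible)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] == 0:
        return np.nan
    return float(v[np.searchsorted(cw, q * cw[-1], side="left").clip(0, v.size - 1)])


def scalogram(
    cmap: ContactMap,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
    max_s: float | None = None,
    score: str | None = None,
) -> pd.DataFrame:
    """Per-bin quantiles of the cis contact-distance distribution.

    Distances are score-weighted (balanced scores when available, raw
    counts otherwise) and capped at ``max_s``.  Bins without cis contacts
    get NaN.  Returns one column per quantile, plus bin coordinates; the
    tracks are also attached to the map's bin table as ``scalogram_q*``.
    """
    if score is None:
        score = "balanced" if "balanced" in cmap.layers else "count"
    w = np.nan_to_num(np.asarray(cmap.interactions.layer(score), dtype=float))
    bt = cmap.bintable
    ints = cmap.interactions
    same = bt.chrom_id[ints.bin1_id] == bt.chrom_id[ints.bin2_id]
    b1, b2, w = ints.bin1_id[same], ints.bin2_id[same], w[same]
    dist = (b2 - b1).astype(float) * bt.resolution
    if max_s is not None:
        keep = dist <= max_s
        b1, b2, w, dist = b1[keep], b2[keep], w[keep], dist[keep]
    n = bt.n_bins
    tracks = {q: np.full(n, np.nan) for q in quantiles}
    # contacts of bin i: records where i is either anchor
    both_bins = np.concatenate([b1, b2])
    both_d = np.concatenate([dist, dist])
    both_w = np.concatenate([w, w])
    order = np.argsort(both_bins, kind="stable")
    both_bins, both_d, both_w = both_bins[order], both_d[order], both_w[order]
    bounds = np.searchsorted(both_bins, np.arange(n + 1))
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            continue
        for q in quantiles:
            tracks[q][i] = _weighted_quantile(both_d[lo:hi], both_w[lo:hi], q)
    names = np.asarray(cmap.layout.names, dtype=object)
    df = pd.DataFrame(
        {"chrom": names[bt.chrom_id], "start": bt.start, "end": bt.end}
    )
    for q in quantiles:
        col = f"scalogram_q{int(round(q * 100))}"
        df[col] = tracks[q]
        bt.set_track(col, tracks[q])
    return df


def virtual_4c(
    cmap: ContactMap,
    viewpoint: "str | Region",
    score: str = "balanced",
    normalize: bool = True,
) -> pd.DataFrame:
    """Contact profile of one viewpoint against the rest of the genome.

    ``track[i] = sum over viewpoint bins v of score(v, i)``; when
    ``normalize``, each chromosome's profile is divided by its total so
    viewpoints of different coverage are comparable.
    """
    region = parse_region(viewpoint, cmap.layout)
    bt = cmap.bintable
    vbins = bt.region_bins(region)
    if bt.weights is not None and not np.isfinite(bt.weights[vbins]).any():
        raise ValueError("viewpoint overlaps no valid bin")
    if score not in cmap.layers:
        raise KeyError(f"layer {score!r} not present")
    vals = np.nan_to_num(np.asarray(cmap.interactions.layer(score), dtype=float))
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    track = np.zeros(bt.n_bins)
    in1 = np.isin(b1, vbins)
    in2 = np.isin(b2, vbins)
    np.add.at(track, b2[in1], vals[in1])
    np.add.at(track, b1[in2 & ~in1], vals[in2 & ~in1])
    # symmetric: a record with both ends inside the viewpoint counts once
    if normalize:
        for chrom in cmap.layout.names:
            sl = bt.chrom_slice(chrom)
            tot = track[sl].sum()
            if tot > 0:
                track[sl] = track[sl] / tot
    names = np.asarray(cmap.layout.names, dtype=object)
    return pd.DataFrame(
        {
            "chrom": names[bt.chrom_id],
            "start": bt.start,
            "end": bt.end,
            "score": track,
        }
    )


def _smooth(mat: np.ndarray, h: int) -> np.ndarray:
    if h <= 0:
        return mat
    return ndimage.uniform_filter(mat, size=2 * h + 1, mode="constant")


def scc(
    a: ContactMap,
    b: ContactMap,
    h: int = 1,
    max_s: float = 5_000_000,
) -> SccResult:
    """Stratum-adjusted correlation coefficient between two maps.

    Dense per-chromosome cis count matrices are mean-filtered with a
    (2h+1)^2 window; strata are bin offsets 1..max_s/resolution; each
    stratum contributes a Pearson correlation weighted by
    n_k * sd_k(a) * sd_k(b).  The genome-level SCC averages chromosome
    SCCs weighted by chromosome bin count.
    """
    if a.layout != b.layout or a.resolution != b.resolution:
        raise ValueError("maps differ in layout or resolution")
    res = a.resolution
    max_d = max(1, int(max_s // res))
    per_chrom: dict[str, float] = {}
    chrom_w: dict[str, int] = {}
    strata_rows = []
    for chrom in a.layout.names:
        region = Region(chrom, 0, a.layout.length(chrom))
        da = _smooth(a._shallow(focus=region).dense("count"), h)
        db = _smooth(b._shallow(focus=region).dense("count"), h)
        n = da.shape[0]
        num = den = 0.0
        for d in range(1, min(max_d, n - 1) + 1):
            xa = np.diagonal(da, d)
            xb = np.diagonal(db, d)
            nk = xa.size
            if nk < 2:
                continue
            sda, sdb = xa.std(), xb.std()
            if sda == 0 or sdb == 0:
                continue  # degenerate stratum: weight 0
            if np.array_equal(xa, xb):
                rho = 1.0  # exact, avoids float round-off on self-comparison
            else:
                rho = float(np.corrcoef(xa, xb)[0, 1])
            wk = nk * sda * sdb
            num += wk * rho
            den += wk
            strata_rows.append((chrom, d, rho, wk, nk))
        if den > 0:
            per_chrom[chrom] = num / den
            chrom_w[chrom] = n
    if not per_chrom:
        raise ValueError("no informative strata")
    total_w = sum(chrom_w.values())
    overall = sum(per_chrom[c] * chrom_w[c] for c in per_chrom) / total_w
    df = pd.DataFrame(strata_rows, columns=["chrom", "stratum", "rho", "weight", "n"])
    return SccResult(float(overall), df, per_chrom)
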