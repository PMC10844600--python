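"""Static rendering of contact maps and derived statistics.

All functions write PNG/SVG/PDF through the matplotlib Agg backend and are
deterministic for fixed inputs (SVG hash salt and date metadata pinned),
so rendering twice yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.colors import LogNorm, Normalize, TwoSlopeNorm  # noqa: E402

from .model import ContactMap  # noqa: E402
from .ops import AggregatedMap, aggregate  # noqa: E402
from .stats import PsProfile  # noqa: E402
from .features import SaddleData  # noqa: E402

__all__ = ["RenderSpec", "render_matrix", "render_stats", "normalize_for_render"]

plt.rcParams["svg.hashsalt"] = "hicmap"


@dataclass
class RenderSpec:
    """Options for :func:`render_matrix`."""

    score: str = "count"
    scale: str = "log10"  # log10 | linear | log2-diverging
    vrange: tuple[float, float] | None = None
    cmap: str | None = None
    mode: str = "square"  # square | horizontal
    max_distance: float | None = None  # required for horizontal mode
    overlays: dict = field(default_factory=dict)  # borders/loops/compartments
    comparison: ContactMap | None = None  # drawn in the lower triangle
    figsize: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        if self.mode == "horizontal" and self.max_distance is None:
            raise ValueError("horizontal mode requires max_distance")
        if self.cmap is None:
            self.cmap = "RdBu_r" if self.scale == "log2-diverging" else "Reds"


def _norm(values: np.ndarray, spec: RenderSpec):
    finite = values[np.isfinite(values)]
    if spec.vrange is not None:
        vmin, vmax = spec.vrange
    elif finite.size:
        vmin, vmax = float(finite.min()), float(finite.max())
    else:
        vmin, vmax = 0.0, 1.0
    if spec.scale == "log10":
        pos = finite[finite > 0]
        vmin = max(vmin, float(pos.min())) if pos.size else 1e-3
        vmax = max(vmax, vmin * 10)
        return LogNorm(vmin=vmin, vmax=vmax)
    if spec.scale == "log2-diverging":
        limit = max(abs(vmin), abs(vmax), 1e-9)
        return TwoSlopeNorm(vmin=-limit, vcenter=0.0, vmax=limit)
    return Normalize(vmin=vmin, vmax=vmax)


def normalize_for_render(values: np.ndarray, spec: RenderSpec) -> np.ndarray:
    """The [0, 1] normalization applied before color mapping (exposed so the
    mapping can be verified independently of the image backend)."""
    return np.asarray(_norm(values, spec)(np.ma.masked_invalid(values)))


def _save(fig, out_path: str) -> str:
    fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
    plt.close(fig)
    return str(out_path)


def render_matrix(cmap: ContactMap, spec: RenderSpec, out_path: str) -> str:
    """Heatmap of a score layer: square (optionally with a second map in
    the lower triangle), or the 45-degree rotated horizontal band."""
    mat = cmap.dense(spec.score)
    if spec.comparison is not None:
        other = spec.comparison.dense(spec.score)
        if other.shape != mat.shape:
            raise ValueError("comparison map has a different shape")
        lower = np.tril_indices(mat.shape[0], -1)
        mat = mat.copy()
        mat[lower] = other[lower]
    norm = _norm(mat, spec)
    fig, ax = plt.subplots(figsize=spec.figsize)
    if spec.mode == "square":
        ax.imshow(mat, norm=norm, cmap=spec.cmap, interpolation="none")
        ax.set_xlabel("bin")
        ax.set_ylabel("bin")
    elif spec.mode == "horizontal":
        n = mat.shape[0]
        kmax = max(1, int(spec.max_distance // cmap.resolution))
        band = np.full((kmax + 1, n), np.nan)
        for k in range(kmax + 1):
            d = np.diagonal(mat, k)
            band[kmax - k, k // 2 : k // 2 + d.size] = d
        ax.imshow(band, norm=norm, cmap=spec.cmap, interpolation="none", aspect="auto")
        ax.set_xlabel("bin")
        ax.set_ylabel("distance (bins)")
    else:
        raise ValueError("mode must be square or horizontal")
    _draw_overlays(ax, cmap, spec)
    ax.set_title(f"{spec.score} ({spec.scale})")
    fig.colorbar(ax.images[0], ax=ax, shrink=0.7)
    return _save(fig, out_path)


def _feature_bin(cmap: ContactMap, region) -> int:
    sl = cmap.bintable.chrom_slice(region.chrom)
    return sl.start + (region.start + region.end) // 2 // cmap.resolution


def _draw_overlays(ax, cmap: ContactMap, spec: RenderSpec) -> None:
    if spec.mode != "square":
        return
    offset = 0
    if cmap.focus is not None and not isinstance(cmap.focus, tuple):
        offset = cmap.bintable.region_bins(cmap.focus)[0]
    borders = spec.overlays.get("borders")
    if borders is not None:
        for r in borders.regions:
            b = _feature_bin(cmap, r) - offset
            ax.plot([b], [b], marker="d", ms=6, color="blue", mfc="none")
    loops = spec.overlays.get("loops")
    if loops is not None:
        for r1, r2 in zip(loops.regions, loops.regions2):
            i = _feature_bin(cmap, r1) - offset
            j = _feature_bin(cmap, r2) - offset
            ax.plot([j], [i], marker="o", ms=8, color="black", mfc="none")
    comps = spec.overlays.get("compartments")
    if comps is not None:
        for r, lab in zip(comps.regions, comps.labels or []):
            lo = (cmap.bintable.chrom_slice(r.chrom).start
                  + r.start // cmap.resolution - offset)
            hi = lo + max(1, (r.end - r.start) // cmap.resolution)
            color = "firebrick" if lab == "A" else "steelblue"
            ax.plot([lo, hi], [-1.5, -1.5], lw=4, color=color, clip_on=False)


def render_stats(obj, out_path: str, **kwargs) -> str:
    """Render a PsProfile (log-log curve + slope subpanel), SaddleData
    (q x q heatmap with corner annotations), AggregatedMap (centered
    pileup heatmap) or a scalogram data frame (quantile ribbon)."""
    if isinstance(obj, PsProfile):
        return _render_ps(obj, out_path)
    if isinstance(obj, SaddleData):
        return _render_saddle(obj, out_path)
    if isinstance(obj, AggregatedMap):
        return _render_aggregate(obj, out_path, kwargs.get("stat", "mean"))
    try:
        import pandas as pd

        if isinstance(obj, pd.DataFrame) and any(
            c.startswith("scalogram_q") for c in obj.columns
        ):
            return _render_scalogram(obj, out_path)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"cannot render object of type {type(obj).__name__}")


def _render_ps(prof: PsProfile, out_path: str) -> str:
    if prof.p.size == 0:
        raise ValueError("empty profile")
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(5, 6), sharex=True, height_ratios=[2, 1]
    )
    ax1.loglog(prof.s_mid, prof.p, "-", color="darkred")
    ax1.set_ylabel("P(s)")
    ax2.semilogx(prof.s_mid, prof.slope, "-", color="navy")
    ax2.set_ylabel("slope")
    ax2.set_xlabel("genomic separation s (bp)")
    fig.tight_layout()
    return _save(fig, out_path)


def _render_saddle(sad: SaddleData, out_path: str) -> str:
    if sad.s_matrix.size == 0:
        raise ValueError("empty saddle")
    fig, ax = plt.subplots(figsize=(5, 4.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        img = np.log2(sad.s_matrix)
    lim = np.nanmax(np.abs(img[np.isfinite(img)])) if np.isfinite(img).any() else 1.0
    im = ax.imshow(img, cmap="RdBu_r", vmin=-lim, vmax=lim, interpolation="none")
    # groups ordered from strongest B (low E1) to strongest A (high E1)
    ax.set_xlabel("E1 quantile (B → A)")
    ax.set_ylabel("E1 quantile (B → A)")
    for name, val in sad.corner_summary.items():
        if np.isfinite(val):
            pos = {"BB": (0.02, 0.98), "AA": (0.98, 0.02), "AB": (0.98, 0.98)}[name]
            ax.annotate(
                f"{name}: {val:.2f}",
                xy=pos,
                xycoords="axes fraction",
                ha="right" if pos[0] > 0.5 else "left",
                va="top" if pos[1] > 0.5 else "bottom",
                fontsize=8,
            )
    fig.colorbar(im, ax=ax, label="log2 mean O/E")
    return _save(fig, out_path)


def _render_aggregate(agg: AggregatedMap, out_path: str, stat: str) -> str:
    slice_ = aggregate(agg, stat)
    f = slice_.shape[0] // 2
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(slice_, cmap="RdBu_r", interpolation="none")
    ax.set_xticks([0, f, 2 * f])
    ax.set_xticklabels([f"-{f}", "0", f"+{f}"])
    ax.set_yticks([0, f, 2 * f])
    ax.set_yticklabels([f"-{f}", "0", f"+{f}"])
    ax.set_xlabel("offset (bins)")
    fig.colorbar(im, ax=ax, label=f"{stat} {agg.score_used}")
    return _save(fig, out_path)


def _render_scalogram(df, out_path: str) -> str:
    qcols = sorted(c for c in df.columns if c.startswith("scalogram_q"))
    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(df))
    if len(qcols) >= 2:
        ax.fill_between(
            x, df[qcols[0]], df[qcols[-1]], alpha=0.3, color="steelblue"
        )
    mid = qcols[len(qcols) // 2]
    ax.plot(x, df[mid], color="navy", lw=1)
    ax.set_xlabel("bin")
    ax.set_ylabel("contact distance (bp)")
    fig.tight_layout()
    return _save(fig, out_path)
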