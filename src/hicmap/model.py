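"""Core in-memory model for binned chromosome-conformation contact data.

A :class:`ContactMap` ties together a fixed-resolution genome partition
(:class:`BinTable`), a sparse upper-triangular set of binned interactions
(:class:`InteractionSet`) carrying named score layers, an optional genomic
focus, structural-feature annotations and an optional handle to a
multi-resolution file on disk.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open.  User-facing region strings
``"chrII:1001-2000"`` follow the genome-browser convention (1-based,
inclusive) and are converted on parse; a bare ``"chrII"`` denotes the whole
chromosome.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Region",
    "parse_region",
    "BinTable",
    "InteractionSet",
    "FeatureSet",
    "ContactMap",
]

RESERVED_LAYER = "count"


class NoBackingError(RuntimeError):
    """Raised when a file-backed operation is requested on an in-memory map."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with their lengths in base pairs.

    The declaration order is stable and defines the global coordinate order
    used for bin ids and for the upper-triangular storage of interactions.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_chroms(self) -> int:
        return len(self.names)

    def index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return self.lengths[self.index(chrom)]

    def n_bins(self, resolution: int) -> int:
        return int(sum(-(-l // resolution) for l in self.lengths))

    def bin_offsets(self, resolution: int) -> np.ndarray:
        """Cumulative first global bin id of each chromosome (length n+1)."""
        per = np.array([-(-l // resolution) for l in self.lengths], dtype=np.int64)
        return np.concatenate([[0], np.cumsum(per)])

    def items(self) -> Iterable[tuple[str, int]]:
        return zip(self.names, self.lengths)


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open, validated against a layout."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def validate(self, layout: GenomeLayout) -> "Region":
        if self.end > layout.length(self.chrom):
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout.length(self.chrom)}"
            )
        return self

    def __str__(self) -> str:  # 1-based inclusive, browser style
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def parse_region(spec: "str | Region", layout: GenomeLayout) -> Region:
    """Parse ``"chr"`` or ``"chr:start-end"`` (1-based inclusive) to a Region."""
    if isinstance(spec, Region):
        return spec.validate(layout)
    spec = spec.strip()
    if ":" not in spec:
        return Region(spec, 0, layout.length(spec))
    chrom, _, rng = spec.partition(":")
    lo, _, hi = rng.replace(",", "").partition("-")
    start, end = int(lo) - 1, int(hi)
    return Region(chrom, start, end).validate(layout)


class BinTable:
    """Fixed-resolution partition of a genome into consecutive bins.

    Carries optional per-bin balancing weights (NaN marks bins filtered out
    of downstream statistics; ``weights is None`` means the map has not been
    balanced) and named per-bin tracks such as the compartment eigenvector
    or the insulation score.
    """

    def __init__(self, layout: GenomeLayout, resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.layout = layout
        self.resolution = int(resolution)
        chrom_ids, starts = [], []
        for ci, (_, length) in enumerate(layout.items()):
            s = np.arange(0, length, resolution, dtype=np.int64)
            starts.append(s)
            chrom_ids.append(np.full(s.size, ci, dtype=np.int32))
        self.chrom_id = np.concatenate(chrom_ids)
        self.start = np.concatenate(starts)
        lengths = np.asarray(layout.lengths, dtype=np.int64)
        self.end = np.minimum(self.start + resolution, lengths[self.chrom_id])
        self.weights: np.ndarray | None = None
        self.tracks: dict[str, np.ndarray] = {}

    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def offsets(self) -> np.ndarray:
        return self.layout.bin_offsets(self.resolution)

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.layout.index(chrom)
        off = self.offsets
        return slice(int(off[ci]), int(off[ci + 1]))

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id of a 0-based genomic position."""
        if not 0 <= pos < self.layout.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        ci = self.layout.index(chrom)
        return int(self.offsets[ci] + pos // self.resolution)

    def region_bins(self, region: Region) -> np.ndarray:
        """Global ids of bins overlapping ``region``."""
        region.validate(self.layout)
        off = int(self.offsets[self.layout.index(region.chrom)])
        lo = off + region.start // self.resolution
        hi = off + -(-region.end // self.resolution)
        return np.arange(lo, hi, dtype=np.int64)

    def set_track(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_bins,):
            raise ValueError(
                f"track {name!r} has {values.size} values for {self.n_bins} bins"
            )
        self.tracks[name] = values

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.layout.names, dtype=object)
        df = pd.DataFrame(
            {"chrom": names[self.chrom_id], "start": self.start, "end": self.end}
        )
        if self.weights is not None:
            df["weight"] = self.weights
        for name, v in self.tracks.items():
            df[name] = v
        return df

    def copy(self) -> "BinTable":
        new = BinTable.__new__(BinTable)
        new.layout = self.layout
        new.resolution = self.resolution
        new.chrom_id = self.chrom_id
        new.start = self.start
        new.end = self.end
        new.weights = None if self.weights is None else self.weights.copy()
        new.tracks = {k: v.copy() for k, v in self.tracks.items()}
        return new


class InteractionSet:
    """Sparse upper-triangular set of binned interactions with score layers.

    Records are sorted by ``(bin1_id, bin2_id)`` with ``bin1_id <= bin2_id``
    and no duplicates.  The ``"count"`` layer (raw contact counts) is always
    present; derived layers (``balanced``, ``expected``, ``oe``, user layers)
    are optional and share the record order.
    """

    def __init__(
        self,
        bin1_id: np.ndarray,
        bin2_id: np.ndarray,
        scores: Mapping[str, np.ndarray],
        *,
        canonical: bool = False,
    ):
        b1 = np.asarray(bin1_id, dtype=np.int64)
        b2 = np.asarray(bin2_id, dtype=np.int64)
        scores = {k: np.asarray(v) for k, v in scores.items()}
        if RESERVED_LAYER not in scores:
            raise ValueError("scores must contain a 'count' layer")
        for k, v in scores.items():
            if v.shape != b1.shape:
                raise ValueError(f"score layer {k!r} length mismatch")
        if not canonical:
            lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
            order = np.lexsort((hi, lo))
            b1, b2 = lo[order], hi[order]
            scores = {k: v[order] for k, v in scores.items()}
            if b1.size and np.any((np.diff(b1) == 0) & (np.diff(b2) == 0)):
                raise ValueError("duplicate (bin1, bin2) records")
        self.bin1_id, self.bin2_id, self.scores = b1, b2, scores

    def __len__(self) -> int:
        return self.bin1_id.size

    @property
    def layers(self) -> list[str]:
        return list(self.scores)

    def layer(self, name: str) -> np.ndarray:
        if name not in self.scores:
            raise KeyError(
                f"unknown score layer {name!r}; available: {sorted(self.scores)}"
            )
        return self.scores[name]

    def with_layer(self, name: str, values: np.ndarray) -> "InteractionSet":
        values = np.asarray(values)
        if values.shape != self.bin1_id.shape:
            raise ValueError(
                f"layer {name!r}: {values.size} values for {len(self)} records"
            )
        scores = dict(self.scores)
        scores[name] = values
        return InteractionSet(self.bin1_id, self.bin2_id, scores, canonical=True)

    def drop_layers(self, names: Iterable[str]) -> "InteractionSet":
        keep = {k: v for k, v in self.scores.items() if k not in set(names)}
        return InteractionSet(self.bin1_id, self.bin2_id, keep, canonical=True)

    def select(self, mask: np.ndarray) -> "InteractionSet":
        return InteractionSet(
            self.bin1_id[mask],
            self.bin2_id[mask],
            {k: v[mask] for k, v in self.scores.items()},
            canonical=True,
        )


@dataclass
class FeatureSet:
    """Annotated structural features: borders, loops, compartments or custom.

    ``regions`` holds one Region per record for border/compartment kinds; for
    loops, ``regions2`` holds the second anchor (anchor1 <= anchor2 in global
    order).  ``scores`` and ``labels`` are per-record.
    """

    kind: str
    regions: list[Region]
    scores: np.ndarray
    labels: list[str] | None = None
    regions2: list[Region] | None = None

    KINDS = ("border", "loop", "compartment", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.kind == "loop" and self.regions2 is None:
            raise ValueError("loop features need two anchors")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.regions),):
            raise ValueError("scores length mismatch")

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "chrom": [r.chrom for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
        }
        if self.regions2 is not None:
            rows["chrom2"] = [r.chrom for r in self.regions2]
            rows["start2"] = [r.start for r in self.regions2]
            rows["end2"] = [r.end for r in self.regions2]
        rows["score"] = self.scores
        if self.labels is not None:
            rows["label"] = self.labels
        return pd.DataFrame(rows)


class ContactMap:
    """A binned, possibly file-backed, set of genomic interactions.

    Parameters
    ----------
    bintable
        Genome partition at a fixed resolution.
    interactions
        Upper-triangular sparse interactions with at least a raw ``count``
        score layer.
    focus
        Optional Region or (Region, Region) pair recording what was fetched.
    backing
        Optional handle to the multi-resolution file this map was read from;
        required for :meth:`refocus` and file-backed :meth:`zoom`.
    """

    def __init__(
        self,
        bintable: BinTable,
        interactions: InteractionSet,
        *,
        focus=None,
        metadata: dict | None = None,
        features: dict[str, FeatureSet] | None = None,
        backing=None,
    ):
        if len(interactions) and interactions.bin2_id.max() >= bintable.n_bins:
            raise ValueError("interaction bin ids exceed bin table")
        self.bintable = bintable
        self.interactions = interactions
        self.focus = focus
        self.metadata = dict(metadata or {})
        self.features = dict(features or {})
        self.backing = backing

    # -- basic accessors ---------------------------------------------------
    @property
    def layout(self) -> GenomeLayout:
        return self.bintable.layout

    @property
    def resolution(self) -> int:
        return self.bintable.resolution

    @property
    def layers(self) -> list[str]:
        return self.interactions.layers

    def __repr__(self) -> str:
        focus = "genome-wide" if self.focus is None else str(self.focus)
        return (
            f"<ContactMap {focus} @ {self.resolution} bp | "
            f"{len(self.interactions)} records | layers {self.layers}>"
        )

    def _shallow(self, **kwargs) -> "ContactMap":
        new = ContactMap.__new__(ContactMap)
        new.bintable = kwargs.get("bintable", self.bintable)
        new.interactions = kwargs.get("interactions", self.interactions)
        new.focus = kwargs.get("focus", self.focus)
        new.metadata = dict(kwargs.get("metadata", self.metadata))
        new.features = dict(kwargs.get("features", self.features))
        new.backing = kwargs.get("backing", self.backing)
        return new

    # -- operations --------------------------------------------------------
    def refocus(self, region) -> "ContactMap":
        """Re-fetch the map from its file backing over a new region (or a
        (region, region) pair for a trans block)."""
        if self.backing is None:
            raise NoBackingError(
                "refocus needs a file-backed map; this map is in-memory only"
            )
        return self.backing.fetch(self.resolution, focus=region)

    def zoom(self, resolution: int) -> "ContactMap":
        """Change resolution: re-fetch for file-backed maps, coarsen by
        summing raw counts for in-memory maps (derived layers are dropped
        and flagged stale; weights are resolution-specific)."""
        resolution = int(resolution)
        if resolution == self.resolution:
            return self._shallow()
        if self.backing is not None:
            if resolution not in self.backing.resolutions:
                raise ValueError(
                    f"resolution {resolution} not in file; available: "
                    f"{self.backing.resolutions}"
                )
            return self.backing.fetch(resolution, focus=self.focus)
        if resolution % self.resolution != 0:
            raise ValueError(
                f"in-memory zoom needs an integer multiple of {self.resolution}, "
                f"got {resolution}"
            )
        coarse = BinTable(self.layout, resolution)
        # monotone fine->coarse bin map keeps upper-triangularity
        fine2coarse = (
            coarse.offsets[self.bintable.chrom_id]
            + self.bintable.start // resolution
        ).astype(np.int64)
        b1 = fine2coarse[self.interactions.bin1_id]
        b2 = fine2coarse[self.interactions.bin2_id]
        key = b1 * coarse.n_bins + b2
        uniq, inv = np.unique(key, return_inverse=True)
        counts = np.bincount(
            inv, weights=self.interactions.layer(RESERVED_LAYER), minlength=uniq.size
        )
        ints = InteractionSet(
            uniq // coarse.n_bins,
            uniq % coarse.n_bins,
            {RESERVED_LAYER: counts.astype(np.int64)},
            canonical=True,
        )
        meta = dict(self.metadata)
        if len(self.layers) > 1:
            meta["stale_layers"] = sorted(set(self.layers) - {RESERVED_LAYER})
        return ContactMap(coarse, ints, focus=self.focus, metadata=meta)

    def set_score(self, name: str, values) -> "ContactMap":
        """Attach a named score layer (e.g. an externally computed log2
        fold-change) without mutating the original map."""
        if name == RESERVED_LAYER:
            raise ValueError("the raw 'count' layer cannot be overwritten")
        return self._shallow(interactions=self.interactions.with_layer(name, values))

    # -- coercions ---------------------------------------------------------
    def _scope_bins(self):
        """Global bin ids of the rows/cols of the dense form."""
        if self.focus is None:
            n = self.bintable.n_bins
            ids = np.arange(n, dtype=np.int64)
            return ids, ids
        if isinstance(self.focus, Region):
            ids = self.bintable.region_bins(self.focus)
            return ids, ids
        r1, r2 = self.focus
        return self.bintable.region_bins(r1), self.bintable.region_bins(r2)

    def dense(self, layer: str = RESERVED_LAYER) -> np.ndarray:
        """Dense symmetric matrix over the focus scope.

        Counts fill absent records with 0; other layers use NaN so filtered
        or undefined entries stay distinguishable.  The diagonal is stored
        once and mirrored without doubling.
        """
        values = np.asarray(self.interactions.layer(layer), dtype=float)
        rows, cols = self._scope_bins()
        fill = 0.0 if layer == RESERVED_LAYER else np.nan
        mat = np.full((rows.size, cols.size), fill)
        b1, b2 = self.interactions.bin1_id, self.interactions.bin2_id
        # scope bins are always contiguous id ranges, so position = id - first
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        upper = (b1 >= r0) & (b1 < r1) & (b2 >= c0) & (b2 < c1)
        mat[b1[upper] - r0, b2[upper] - c0] = values[upper]
        lower = (b2 >= r0) & (b2 < r1) & (b1 >= c0) & (b1 < c1)
        mat[b2[lower] - r0, b1[lower] - c0] = values[lower]
        return mat

    def sparse(self, layer: str = RESERVED_LAYER):
        """Upper-triangular scipy COO matrix over the full bin table."""
        from scipy import sparse as sp

        n = self.bintable.n_bins
        return sp.coo_matrix(
            (
                self.interactions.layer(layer),
                (self.interactions.bin1_id, self.interactions.bin2_id),
            ),
            shape=(n, n),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per record with bin coordinates and every score layer."""
        bt = self.bintable
        names = np.asarray(self.layout.names, dtype=object)
        b1, b2 = self.interactions.bin1_id, self.interactions.bin2_id
        df = pd.DataFrame(
            {
                "chrom1": names[bt.chrom_id[b1]],
                "start1": bt.start[b1],
                "end1": bt.end[b1],
                "chrom2": names[bt.chrom_id[b2]],
                "start2": bt.start[b2],
                "end2": bt.end[b2],
                "bin1_id": b1,
                "bin2_id": b2,
            }
        )
        for name, v in self.interactions.scores.items():
            df[name] = v
        return df

    def coerce(self, form: str, layer: str = RESERVED_LAYER):
        if form == "dense":
            return self.dense(layer)
        if form == "sparse-triplet":
            return self.sparse(layer)
        if form == "table":
            return self.to_frame()
        raise ValueError("form must be dense, sparse-triplet or table")

    def total(self, layer: str = RESERVED_LAYER) -> float:
        return float(np.nansum(self.interactions.layer(layer)))

    def copy(self) -> "ContactMap":
        return self._shallow(
            bintable=self.bintable.copy(),
            interactions=InteractionSet(
                self.interactions.bin1_id.copy(),
                self.interactions.bin2_id.copy(),
                {k: v.copy() for k, v in self.interactions.scores.items()},
                canonical=True,
            ),
            metadata=_copy.deepcopy(self.metadata),
        )
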