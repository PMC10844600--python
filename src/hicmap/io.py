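"""Readers and writers for on-disk contact data.

Supported formats:

* ``.cool`` / ``.mcool`` — HDF5 containers following the cooler schema
  (``chroms``, ``bins``, ``pixels`` and ``indexes`` tables, with a
  ``bin1_offset`` index used for region queries).  Weights are stored
  multiplicatively (balanced score = w_i * w_j * count); a root attribute
  records this convention.
* HiC-Pro — a three-column sparse matrix text file (bin_i, bin_j, count,
  1-based bin ids) plus a BED-like regions file of bin coordinates.
* 4DN ``.pairs`` — read-level contacts, plain or gzip-compressed, with the
  layout rebuilt from ``#chromsize`` header lines.  Positions are 1-based
  in the file.
* bedGraph export of per-bin tracks; BED / BEDPE-like feature lists.

The binary ``.hic`` format is intentionally not parsed; opening one raises
an explicit error suggesting conversion to ``.cool``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .model import (
    BinTable,
    ContactMap,
    FeatureSet,
    GenomeLayout,
    InteractionSet,
    Region,
    parse_region,
)

__all__ = [
    "ContactFileHandle",
    "PairsTable",
    "UnsupportedFormatError",
    "open_contact_file",
    "fetch",
    "write_cool",
    "read_hicpro",
    "write_hicpro",
    "read_pairs",
    "write_pairs",
    "bin_pairs",
    "export_track",
    "read_bedgraph_track",
    "read_bed_features",
    "write_bed_features",
    "read_bedpe_features",
    "write_bedpe_features",
]

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


class UnsupportedFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cool / mcool
# ---------------------------------------------------------------------------

def _write_cool_group(grp: h5py.Group, cmap: ContactMap) -> None:
    bt, ints = cmap.bintable, cmap.interactions
    layout = cmap.layout
    n_bins = bt.n_bins
    counts = np.asarray(ints.layer("count"))
    chroms = grp.create_group("chroms")
    chroms.create_dataset(
        "name", data=np.array(layout.names, dtype=h5py.string_dtype())
    )
    chroms.create_dataset("length", data=np.asarray(layout.lengths, dtype=np.int64))
    bins = grp.create_group("bins")
    bins.create_dataset("chrom", data=bt.chrom_id.astype(np.int32))
    bins.create_dataset("start", data=bt.start.astype(np.int64))
    bins.create_dataset("end", data=bt.end.astype(np.int64))
    if bt.weights is not None:
        bins.create_dataset("weight", data=bt.weights.astype(np.float64))
    pixels = grp.create_group("pixels")
    pixels.create_dataset("bin1_id", data=ints.bin1_id)
    pixels.create_dataset("bin2_id", data=ints.bin2_id)
    pixels.create_dataset("count", data=np.rint(counts).astype(np.int64))
    indexes = grp.create_group("indexes")
    indexes.create_dataset(
        "chrom_offset", data=layout.bin_offsets(bt.resolution).astype(np.int64)
    )
    indexes.create_dataset(
        "bin1_offset",
        data=np.searchsorted(ints.bin1_id, np.arange(n_bins + 1)).astype(np.int64),
    )
    grp.attrs["format"] = "HDF5::Cooler"
    grp.attrs["format-version"] = 3
    grp.attrs["bin-size"] = bt.resolution
    grp.attrs["bin-type"] = "fixed"
    grp.attrs["nbins"] = n_bins
    grp.attrs["nchroms"] = layout.n_chroms
    grp.attrs["nnz"] = len(ints)
    grp.attrs["sum"] = int(np.rint(counts.sum())) if counts.size else 0
    grp.attrs["divisive-weights"] = False
    grp.attrs["generated-by"] = "hicmap"


def write_cool(path: str, maps, multi: bool = False) -> str:
    """Write one ContactMap (``.cool``) or several resolutions (``.mcool``).

    ``maps`` is a single ContactMap, or an iterable of them when
    ``multi=True``; all maps must share the same genome layout.  Counts
    round-trip bit-exactly; weights to float64 precision.
    """
    if isinstance(maps, ContactMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to write")
    layout = maps[0].layout
    if any(m.layout != layout for m in maps):
        raise ValueError("all maps must share a genome layout")
    if not multi and len(maps) != 1:
        raise ValueError("a single-resolution .cool holds exactly one map")
    with h5py.File(path, "w") as f:
        if multi:
            for m in sorted(maps, key=lambda m: m.resolution):
                grp = f.create_group(f"resolutions/{m.resolution}")
                _write_cool_group(grp, m)
            f.attrs["format"] = "HDF5::MCOOL"
            f.attrs["format-version"] = 2
        else:
            _write_cool_group(f["/"], maps[0])
    return path


@dataclass
class ContactFileHandle:
    """Read-only pointer to a disk-stored contact matrix.

    Lists the available resolutions and the genome layout without loading
    any pixels; :meth:`fetch` performs the actual (random-access) import.
    """

    path: str
    format: str
    resolutions: list[int]
    layout: GenomeLayout
    metadata: dict = field(default_factory=dict)
    _regions_path: str | None = None

    def _group(self, f: h5py.File, resolution: int) -> h5py.Group:
        if resolution not in self.resolutions:
            raise ValueError(
                f"resolution {resolution} not available; file has "
                f"{self.resolutions}"
            )
        return f[f"resolutions/{resolution}"] if self.format == "mcool" else f["/"]

    def fetch(self, resolution: int | None = None, focus=None) -> ContactMap:
        """Import a ContactMap, optionally restricted to a region or a
        (region, region) pair.

        Raw counts are always loaded; if the file stores bin weights, the
        ``balanced`` layer w_i * w_j * c_ij is materialized alongside.
        """
        if resolution is None:
            resolution = self.resolutions[0]
        resolution = int(resolution)
        if self.format == "hicpro":
            cmap = read_hicpro(self.path, self._regions_path)
            if cmap.resolution != resolution:
                raise ValueError(
                    f"resolution {resolution} not available; file has "
                    f"{self.resolutions}"
                )
            return _restrict(cmap, focus, backing=self)
        with h5py.File(self.path, "r") as f:
            grp = self._group(f, resolution)
            bt = BinTable(self.layout, resolution)
            bins = grp["bins"]
            if "weight" in bins:
                bt.weights = bins["weight"][:].astype(float)
            pix = grp["pixels"]
            if focus is not None:
                b1, b2, counts = _query_pixels(grp, bt, focus)
            else:
                b1 = pix["bin1_id"][:]
                b2 = pix["bin2_id"][:]
                counts = pix["count"][:]
        scores = {"count": counts}
        if bt.weights is not None:
            scores["balanced"] = bt.weights[b1] * bt.weights[b2] * counts
        ints = InteractionSet(b1, b2, scores, canonical=True)
        focus_r = _parse_focus(focus, self.layout)
        return ContactMap(
            bt,
            ints,
            focus=focus_r,
            metadata={"path": self.path, "resolution": resolution},
            backing=self,
        )


def _parse_focus(focus, layout):
    if focus is None:
        return None
    if isinstance(focus, (tuple, list)):
        return tuple(parse_region(r, layout) for r in focus)
    return parse_region(focus, layout)


def _query_pixels(grp, bt: BinTable, focus):
    """Region query through the bin1_offset index."""
    focus = _parse_focus(focus, bt.layout)
    if isinstance(focus, Region):
        ranges = [(focus, focus)]
    else:
        r1, r2 = focus
        ranges = [(r1, r2), (r2, r1)]
    offsets = grp["indexes"]["bin1_offset"][:]
    pix = grp["pixels"]
    parts = []
    for ra, rb in ranges:
        ids_a = bt.region_bins(ra)
        ids_b = bt.region_bins(rb)
        lo, hi = int(offsets[ids_a[0]]), int(offsets[ids_a[-1] + 1])
        if hi <= lo:
            continue
        b1 = pix["bin1_id"][lo:hi]
        b2 = pix["bin2_id"][lo:hi]
        c = pix["count"][lo:hi]
        keep = (b2 >= ids_b[0]) & (b2 <= ids_b[-1])
        parts.append((b1[keep], b2[keep], c[keep]))
    if not parts:
        empty = np.array([], dtype=np.int64)
        return empty, empty, empty
    b1 = np.concatenate([p[0] for p in parts])
    b2 = np.concatenate([p[1] for p in parts])
    c = np.concatenate([p[2] for p in parts])
    # the two orientations of a trans query may overlap near the diagonal
    key = b1 * bt.n_bins + b2
    key, idx = np.unique(key, return_index=True)
    return b1[idx], b2[idx], c[idx]


def _restrict(cmap: ContactMap, focus, backing=None) -> ContactMap:
    focus_r = _parse_focus(focus, cmap.layout)
    if focus_r is None:
        cmap.backing = backing
        return cmap
    bt = cmap.bintable
    b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
    if isinstance(focus_r, Region):
        ids = bt.region_bins(focus_r)
        mask = (b1 >= ids[0]) & (b1 <= ids[-1]) & (b2 >= ids[0]) & (b2 <= ids[-1])
    else:
        ids1 = bt.region_bins(focus_r[0])
        ids2 = bt.region_bins(focus_r[1])
        in1 = lambda b: (b >= ids1[0]) & (b <= ids1[-1])  # noqa: E731
        in2 = lambda b: (b >= ids2[0]) & (b <= ids2[-1])  # noqa: E731
        mask = (in1(b1) & in2(b2)) | (in2(b1) & in1(b2))
    out = ContactMap(
        bt,
        cmap.interactions.select(mask),
        focus=focus_r,
        metadata=cmap.metadata,
        backing=backing,
    )
    return out


def open_contact_file(path: str, format: str | None = None, regions: str | None = None) -> ContactFileHandle:
    """Open a contact matrix file and return a read-only handle.

    The format is sniffed from magic bytes / extension when not given.
    ``regions`` is required for HiC-Pro matrix files.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = _sniff_format(path)
    if format == "hic":
        raise UnsupportedFormatError(
            "binary .hic files are not supported; convert to .cool first "
            "(e.g. with hic2cool) and re-open"
        )
    if format in ("cool", "mcool"):
        with h5py.File(path, "r") as f:
            if "resolutions" in f:
                format = "mcool"
                resolutions = sorted(int(k) for k in f["resolutions"])
                grp = f[f"resolutions/{resolutions[0]}"]
            else:
                format = "cool"
                grp = f["/"]
                resolutions = [int(grp.attrs["bin-size"])]
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in grp["chroms"]["name"][:]
            ]
            lengths = grp["chroms"]["length"][:].tolist()
            meta = {
                k: v
                for k, v in grp.attrs.items()
                if isinstance(v, (str, int, float, np.integer, np.floating, np.bool_))
            }
        return ContactFileHandle(
            path, format, resolutions, GenomeLayout(tuple(names), tuple(lengths)), meta
        )
    if format == "hicpro":
        if regions is None:
            raise ValueError("HiC-Pro matrices need a companion regions file")
        cmap = read_hicpro(path, regions)
        return ContactFileHandle(
            path,
            "hicpro",
            [cmap.resolution],
            cmap.layout,
            {},
            _regions_path=regions,
        )
    raise UnsupportedFormatError(f"unknown contact file format for {path!r}")


def _sniff_format(path: str) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:3] == b"HIC":
        return "hic"
    if magic == b"\x89HDF":
        return "cool"  # cool vs mcool resolved on open
    if path.endswith(".hic"):
        return "hic"
    if path.endswith((".matrix", ".txt", ".tsv")):
        return "hicpro"
    raise UnsupportedFormatError(f"cannot sniff format of {path!r}")


def fetch(handle: ContactFileHandle, resolution: int | None = None, focus=None) -> ContactMap:
    """Module-level convenience wrapper around ``handle.fetch``."""
    return handle.fetch(resolution, focus)


# ---------------------------------------------------------------------------
# HiC-Pro
# ---------------------------------------------------------------------------

def read_hicpro(matrix_path: str, regions_path: str) -> ContactMap:
    """Read a HiC-Pro sparse matrix + regions file pair.

    Bin ids in the matrix file are 1-based (the HiC-Pro convention) and are
    mapped to 0-based global ids in layout order.
    """
    reg = pd.read_csv(
        regions_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "bin_id"],
        dtype={"chrom": str},
    )
    names: list[str] = []
    lengths: list[int] = []
    for chrom, sub in reg.groupby("chrom", sort=False):
        names.append(str(chrom))
        lengths.append(int(sub["end"].max()))
    res = int((reg["end"] - reg["start"]).max())
    layout = GenomeLayout(tuple(names), tuple(lengths))
    bt = BinTable(layout, res)
    if len(reg) != bt.n_bins:
        raise ValueError("regions file does not tile the genome at a fixed resolution")
    # map HiC-Pro bin id -> global bin id in layout order
    order = np.empty(len(reg) + 1, dtype=np.int64)
    name_index = {n: i for i, n in enumerate(names)}
    gids = (
        bt.offsets[reg["chrom"].map(name_index).to_numpy()]
        + reg["start"].to_numpy() // res
    )
    order[:] = -1
    order[reg["bin_id"].to_numpy()] = gids
    mat = pd.read_csv(
        matrix_path, sep=r"\s+", header=None, names=["bin1", "bin2", "count"]
    )
    if not np.issubdtype(mat["count"].dtype, np.integer):
        if not np.allclose(mat["count"], np.rint(mat["count"])):
            raise ValueError("HiC-Pro counts must be integers")
        mat["count"] = np.rint(mat["count"]).astype(np.int64)
    max_id = int(reg["bin_id"].max())
    if mat[["bin1", "bin2"]].to_numpy().max() > max_id or mat[["bin1", "bin2"]].min().min() < 1:
        raise ValueError("matrix references a bin id absent from the regions file")
    b1 = order[mat["bin1"].to_numpy()]
    b2 = order[mat["bin2"].to_numpy()]
    ints = InteractionSet(b1, b2, {"count": mat["count"].to_numpy()})
    return ContactMap(bt, ints, metadata={"path": matrix_path, "format": "hicpro"})


def write_hicpro(cmap: ContactMap, matrix_path: str, regions_path: str) -> None:
    """Write a map as HiC-Pro matrix + regions text files (1-based bin ids)."""
    bt = cmap.bintable
    names = np.asarray(cmap.layout.names, dtype=object)
    reg = pd.DataFrame(
        {
            "chrom": names[bt.chrom_id],
            "start": bt.start,
            "end": bt.end,
            "bin_id": np.arange(1, bt.n_bins + 1),
        }
    )
    reg.to_csv(regions_path, sep="\t", header=False, index=False)
    counts = np.rint(np.asarray(cmap.interactions.layer("count"))).astype(np.int64)
    mat = pd.DataFrame(
        {
            "bin1": cmap.interactions.bin1_id + 1,
            "bin2": cmap.interactions.bin2_id + 1,
            "count": counts,
        }
    )
    mat.to_csv(matrix_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

@dataclass
class PairsTable:
    """Read-level contact records plus the layout from the file header.

    Positions are 1-based, matching the 4DN pairs convention; records are
    upper-triangular by (chromosome order, position).
    """

    df: pd.DataFrame
    layout: GenomeLayout
    columns: list[str] = field(default_factory=lambda: list(PAIRS_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def cis_mask(self) -> np.ndarray:
        return (self.df["chrom1"] == self.df["chrom2"]).to_numpy()

    def cis_distances(self) -> np.ndarray:
        m = self.cis_mask()
        return np.abs(
            self.df.loc[m, "pos2"].to_numpy() - self.df.loc[m, "pos1"].to_numpy()
        )


def _open_text(path: str):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pairs(path: str, max_records: int | None = None) -> PairsTable:
    """Parse a 4DN ``.pairs`` file (plain or gzipped), streaming the body.

    The genome layout is rebuilt from ``#chromsize:`` header lines; extra
    columns beyond the seven mandatory ones are preserved opaquely.
    """
    names: list[str] = []
    lengths: list[int] = []
    columns = list(PAIRS_COLUMNS)
    saw_magic = False
    fh = _open_text(path)
    try:
        pos = None
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                break
            if line.startswith("##"):
                if "pairs format" in line:
                    saw_magic = True
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    _, chrom, length = line.split()
                    names.append(chrom)
                    lengths.append(int(length))
                elif line.startswith("#columns:"):
                    columns = line.split()[1:]
                continue
            fh.seek(pos)
            break
        if not saw_magic:
            raise ValueError(f"{path}: missing '## pairs format' header")
        if not names:
            raise ValueError(f"{path}: no #chromsize header lines")
        df = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            names=columns,
            nrows=max_records,
            dtype={"chrom1": str, "chrom2": str},
        )
    finally:
        fh.close()
    layout = GenomeLayout(tuple(names), tuple(lengths))
    known = set(names)
    for col in ("chrom1", "chrom2"):
        bad = set(df[col].unique()) - known
        if bad:
            raise ValueError(f"{path}: unknown chromosome(s) {sorted(bad)} in body")
    return PairsTable(df, layout, columns)


def write_pairs(pairs: PairsTable, path: str) -> str:
    """Write a PairsTable as a valid 4DN pairs file (gzip if path ends .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#sorted: chr1-chr2-pos1-pos2\n")
        for name, length in pairs.layout.items():
            fh.write(f"#chromsize: {name} {length}\n")
        fh.write("#columns: " + " ".join(pairs.columns) + "\n")
        pairs.df.to_csv(fh, sep="\t", header=False, index=False)
    return str(path)


def bin_pairs(
    pairs: PairsTable,
    resolution: int,
    dedup: bool = True,
    min_cis_distance: int = 0,
) -> ContactMap:
    """Bin read-level pairs into a fixed-resolution ContactMap.

    PCR duplicates (identical chrom1, pos1, strand1, chrom2, pos2, strand2)
    collapse to a single contact when ``dedup``; cis pairs closer than
    ``min_cis_distance`` are dropped (self-religation / dangling-end
    filtering).  Bookkeeping of kept and dropped records lands in the map
    metadata.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    df = pairs.df
    n_input = len(df)
    if dedup:
        df = df.drop_duplicates(
            subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
        )
    n_dup = n_input - len(df)
    cis = (df["chrom1"] == df["chrom2"]).to_numpy()
    dist = np.abs(df["pos2"].to_numpy() - df["pos1"].to_numpy())
    short = cis & (dist < min_cis_distance)
    df = df.loc[~short]
    n_short = int(short.sum())
    bt = BinTable(pairs.layout, resolution)
    name_index = {n: i for i, n in enumerate(pairs.layout.names)}
    c1 = df["chrom1"].map(name_index).to_numpy()
    c2 = df["chrom2"].map(name_index).to_numpy()
    lengths = np.asarray(pairs.layout.lengths, dtype=np.int64)
    for pos, ci in (("pos1", c1), ("pos2", c2)):
        p = df[pos].to_numpy()
        if (p < 1).any() or (p > lengths[ci]).any():
            raise ValueError(f"{pos} outside chromosome bounds")
    # pairs positions are 1-based; bins are 0-based half-open
    b1 = bt.offsets[c1] + (df["pos1"].to_numpy() - 1) // resolution
    b2 = bt.offsets[c2] + (df["pos2"].to_numpy() - 1) // resolution
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    key = lo * bt.n_bins + hi
    uniq, counts = np.unique(key, return_counts=True)
    ints = InteractionSet(
        uniq // bt.n_bins,
        uniq % bt.n_bins,
        {"count": counts.astype(np.int64)},
        canonical=True,
    )
    meta = {
        "n_pairs_input": n_input,
        "n_duplicates_removed": n_dup,
        "n_short_range_removed": n_short,
        "n_pairs_kept": int(len(df)),
    }
    return ContactMap(bt, ints, metadata=meta)


# ---------------------------------------------------------------------------
# tracks and features
# ---------------------------------------------------------------------------

def export_track(bintable: BinTable, track: str, path: str) -> str:
    """Write a per-bin track as 4-column bedGraph (0-based half-open).

    Bins with missing (NaN) values are omitted.
    """
    if track not in bintable.tracks:
        raise KeyError(f"unknown track {track!r}; have {sorted(bintable.tracks)}")
    v = bintable.tracks[track]
    names = np.asarray(bintable.layout.names, dtype=object)
    ok = np.isfinite(v)
    df = pd.DataFrame(
        {
            "chrom": names[bintable.chrom_id[ok]],
            "start": bintable.start[ok],
            "end": bintable.end[ok],
            "value": v[ok],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path


def read_bedgraph_track(path: str, bintable: BinTable, name: str) -> np.ndarray:
    """Re-import a bedGraph written by :func:`export_track` onto a bin table."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    values = np.full(bintable.n_bins, np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        sl = bintable.chrom_slice(str(chrom))
        idx = sl.start + sub["start"].to_numpy() // bintable.resolution
        values[idx] = sub["value"].to_numpy()
    bintable.set_track(name, values)
    return values


def read_bed_features(path: str, layout: GenomeLayout, kind: str = "border") -> FeatureSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    regions = [
        Region(str(r[0]), int(r[1]), int(r[2])).validate(layout)
        for r in df.itertuples(index=False)
    ]
    scores = (
        df[4].to_numpy(dtype=float) if df.shape[1] > 4 else np.zeros(len(df))
    )
    labels = df[3].astype(str).tolist() if df.shape[1] > 3 else None
    return FeatureSet(kind, regions, scores, labels=labels)


def write_bed_features(features: FeatureSet, path: str) -> str:
    df = features.to_frame()
    cols = ["chrom", "start", "end"]
    df["name"] = features.labels if features.labels is not None else "."
    out = df[cols + ["name", "score"]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path


def read_bedpe_features(path: str, layout: GenomeLayout) -> FeatureSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    r1 = [Region(str(r[0]), int(r[1]), int(r[2])).validate(layout) for r in df.itertuples(index=False)]
    r2 = [Region(str(r[3]), int(r[4]), int(r[5])).validate(layout) for r in df.itertuples(index=False)]
    scores = df[6].to_numpy(dtype=float) if df.shape[1] > 6 else np.zeros(len(df))
    return FeatureSet("loop", r1, scores, regions2=r2)


def write_bedpe_features(features: FeatureSet, path: str) -> str:
    if features.kind != "loop":
        raise ValueError("BEDPE export is for loop features")
    df = features.to_frame()
    out = df[["chrom", "start", "end", "chrom2", "start2", "end2", "score"]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path
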