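"""Seeded generators of contact maps and read-level pairs with known truth.

The generative model composes, per bin pair (i, j), an intensity

    Lambda_ij = decay(s_ij) * plaid_ij * domain_ij * loop_ij * bias_i*bias_j

where decay is a truncated power law s^-alpha of the genomic separation,
plaid multiplies (1 + gamma * state_i * state_j) for per-bin +-1
compartment states (cis and trans alike), domain multiplies delta for bin
pairs inside the same TAD, loops multiply a Gaussian-shaped bump of peak
height eta around each planted anchor pair, and bias is an optional
separable per-bin multiplicative field.  Intensities are scaled so cis and
trans totals match ``cis_fraction * n_contacts`` and the remainder, and
counts are drawn independently Poisson (asymptotically equivalent to a
multinomial at fixed total).  Everything is a pure function of
(spec, seed).

Ground truth (states, boundaries, anchors, exponent, bias) is returned in
the same shapes the feature callers output, so tests can compare sets
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BinTable, ContactMap, FeatureSet, GenomeLayout, InteractionSet, Region
from .io import PAIRS_COLUMNS, PairsTable

__all__ = ["SyntheticSpec", "GroundTruth", "synthesize_map", "synthesize_pairs", "spec_from_config"]


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic contact experiment."""

    layout: GenomeLayout
    resolution: int
    n_contacts: int
    alpha: float = 1.0
    s_min: float | None = None  # defaults to one bin / 100 bp for pairs
    s_max: float | None = None  # defaults to the longest chromosome
    cis_fraction: float = 0.9
    compartment_states: np.ndarray | None = None  # per-bin +-1
    plaid_strength: float = 0.0  # gamma
    domain_boundaries: dict[str, list[int]] = field(default_factory=dict)  # bp
    domain_multiplier: float = 1.0  # delta
    loops: list[tuple[Region, Region]] = field(default_factory=list)
    loop_enrichment: float = 1.0  # eta
    bias: np.ndarray | None = None  # per-bin multiplicative
    duplicate_rate: float = 0.0  # pairs only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.compartment_states is not None:
            self.compartment_states = np.asarray(self.compartment_states, dtype=float)
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)


@dataclass
class GroundTruth:
    states: np.ndarray | None
    boundaries: FeatureSet | None
    loops: FeatureSet | None
    alpha: float
    bias: np.ndarray | None
    n_cis_expected: float
    n_trans_expected: float
    intensity_total: float


def _domain_ids(spec: SyntheticSpec, bt: BinTable) -> np.ndarray:
    """Per-bin domain index; domains never span chromosomes."""
    ids = np.zeros(bt.n_bins, dtype=np.int64)
    next_id = 0
    for chrom in spec.layout.names:
        sl = bt.chrom_slice(chrom)
        starts = bt.start[sl]
        cuts = sorted(spec.domain_boundaries.get(chrom, []))
        dom = np.searchsorted(np.asarray(cuts, dtype=float), starts, side="right")
        ids[sl] = dom + next_id
        next_id = ids[sl].max() + 1
    return ids


def _intensity(spec: SyntheticSpec) -> tuple[BinTable, np.ndarray]:
    """Dense symmetric intensity over all bin pairs, scaled to n_contacts."""
    bt = BinTable(spec.layout, spec.resolution)
    n = bt.n_bins
    res = spec.resolution
    chrom_id = bt.chrom_id
    pos = bt.start // res
    same = chrom_id[:, None] == chrom_id[None, :]
    d = np.abs(pos[:, None] - pos[None, :]).astype(float)
    s = np.maximum(d, 1.0) * res
    decay = np.where(same, s ** (-spec.alpha), 0.0)
    lam_cis = decay
    lam_trans = (~same).astype(float)
    plaid = 1.0
    if spec.compartment_states is not None and spec.plaid_strength > 0:
        st = spec.compartment_states
        plaid = 1.0 + spec.plaid_strength * np.outer(st, st)
        plaid = np.maximum(plaid, 0.0)
    lam_cis = lam_cis * plaid
    lam_trans = lam_trans * plaid
    if spec.domain_multiplier != 1.0 and spec.domain_boundaries:
        dom = _domain_ids(spec, bt)
        same_dom = dom[:, None] == dom[None, :]
        lam_cis = lam_cis * np.where(same_dom & same, spec.domain_multiplier, 1.0)
    if spec.loops and spec.loop_enrichment != 1.0:
        bump = np.ones((n, n))
        grid = np.arange(n)
        for r1, r2 in spec.loops:
            i = bt.bin_id(r1.chrom, (r1.start + r1.end) // 2)
            j = bt.bin_id(r2.chrom, (r2.start + r2.end) // 2)
            di = grid[:, None] - i
            dj = grid[None, :] - j
            g = np.exp(-(di**2 + dj**2) / 2.0)
            # peak height eta at (i, j), Gaussian shoulders; mirrored so the
            # factor is symmetric
            factor = 1.0 + (spec.loop_enrichment - 1.0) * np.maximum(g, g.T)
            bump *= factor
        lam_cis = lam_cis * np.where(same, bump, 1.0)
    if spec.bias is not None:
        b = np.outer(spec.bias, spec.bias)
        lam_cis = lam_cis * b
        lam_trans = lam_trans * b
    # scale cis and trans blocks separately to hit the requested split
    iu = np.triu_indices(n)
    cis_mass = lam_cis[iu].sum()
    trans_mass = lam_trans[iu].sum()
    lam = np.zeros((n, n))
    if cis_mass > 0 and spec.cis_fraction > 0:
        lam += lam_cis * (spec.cis_fraction * spec.n_contacts / cis_mass)
    if trans_mass > 0 and spec.cis_fraction < 1:
        lam += lam_trans * ((1 - spec.cis_fraction) * spec.n_contacts / trans_mass)
    if lam[iu].sum() == 0:
        raise ValueError("degenerate spec: all-zero intensity")
    return bt, lam


def _truth(spec: SyntheticSpec, bt: BinTable, lam: np.ndarray) -> GroundTruth:
    boundaries = None
    if spec.domain_boundaries:
        regions, scores = [], []
        for chrom, cuts in spec.domain_boundaries.items():
            for cut in cuts:
                b = bt.bin_id(chrom, min(cut, spec.layout.length(chrom) - 1))
                regions.append(Region(chrom, int(bt.start[b]), int(bt.end[b])))
                scores.append(1.0)
        boundaries = FeatureSet("border", regions, np.array(scores))
    loops = None
    if spec.loops:
        loops = FeatureSet(
            "loop",
            [r1 for r1, _ in spec.loops],
            np.ones(len(spec.loops)),
            regions2=[r2 for _, r2 in spec.loops],
        )
    n = bt.n_bins
    iu = np.triu_indices(n)
    same = bt.chrom_id[:, None] == bt.chrom_id[None, :]
    cis_mass = float(lam[iu][same[iu]].sum())
    trans_mass = float(lam[iu][~same[iu]].sum())
    return GroundTruth(
        spec.compartment_states,
        boundaries,
        loops,
        spec.alpha,
        spec.bias,
        cis_mass,
        trans_mass,
        cis_mass + trans_mass,
    )


def synthesize_map(spec: SyntheticSpec) -> tuple[ContactMap, GroundTruth]:
    """Draw a Poisson contact map from the spec's intensity model."""
    bt, lam = _intensity(spec)
    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(bt.n_bins)
    counts = rng.poisson(lam[iu])
    keep = counts > 0
    ints = InteractionSet(
        iu[0][keep].astype(np.int64),
        iu[1][keep].astype(np.int64),
        {"count": counts[keep].astype(np.int64)},
        canonical=True,
    )
    cmap = ContactMap(bt, ints, metadata={"synthetic": True, "seed": spec.seed})
    return cmap, _truth(spec, bt, lam)


def _draw_powerlaw(rng, n: int, s_min: float, s_max: float, alpha: float) -> np.ndarray:
    """Inverse-transform samples from p(s) ~ s^-alpha on [s_min, s_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return s_min * (s_max / s_min) ** u
    a = 1.0 - alpha
    return (s_min**a + u * (s_max**a - s_min**a)) ** (1.0 / a)


def synthesize_pairs(spec: SyntheticSpec) -> tuple[PairsTable, GroundTruth]:
    """Draw read-level pairs: cis separations from the truncated power law,
    positions uniform along chromosomes, trans pairs uniform; optional PCR
    duplicates injected at ``spec.duplicate_rate`` for dedup tests."""
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout
    lengths = np.asarray(layout.lengths, dtype=float)
    s_min = spec.s_min if spec.s_min is not None else 100.0
    s_max = spec.s_max if spec.s_max is not None else float(lengths.max()) / 2
    n_total = int(spec.n_contacts)
    # a fraction duplicate_rate of the emitted records are PCR duplicates
    n_dup = int(rng.binomial(n_total, spec.duplicate_rate)) if spec.duplicate_rate else 0
    n = n_total - n_dup
    n_cis = int(rng.binomial(n, spec.cis_fraction))
    n_trans = n - n_cis
    rows = []
    # cis
    if n_cis:
        p_chrom = lengths / lengths.sum()
        chrom_idx = rng.choice(layout.n_chroms, size=n_cis, p=p_chrom)
        s = _draw_powerlaw(rng, n_cis, s_min, min(s_max, lengths.min() - 1), spec.alpha)
        # round the separation first so pos2 = pos1 + s never leaves the chromosome
        s = np.minimum(np.rint(s).astype(np.int64), lengths[chrom_idx].astype(np.int64) - 1)
        s = np.maximum(s, 1)
        pos1 = (rng.random(n_cis) * (lengths[chrom_idx] - s)).astype(np.int64) + 1
        pos2 = pos1 + s
        rows.append(
            pd.DataFrame(
                {
                    "chrom1": np.asarray(layout.names, dtype=object)[chrom_idx],
                    "pos1": pos1,
                    "chrom2": np.asarray(layout.names, dtype=object)[chrom_idx],
                    "pos2": pos2,
                }
            )
        )
    if n_trans and layout.n_chroms > 1:
        p_chrom = lengths / lengths.sum()
        c1 = rng.choice(layout.n_chroms, size=n_trans, p=p_chrom)
        c2 = rng.choice(layout.n_chroms, size=n_trans, p=p_chrom)
        redraw = c1 == c2
        while redraw.any():
            c2[redraw] = rng.choice(layout.n_chroms, size=int(redraw.sum()), p=p_chrom)
            redraw = c1 == c2
        swap = c1 > c2
        c1[swap], c2[swap] = c2[swap], c1[swap]
        pos1 = (rng.random(n_trans) * lengths[c1]).astype(np.int64) + 1
        pos2 = (rng.random(n_trans) * lengths[c2]).astype(np.int64) + 1
        rows.append(
            pd.DataFrame(
                {
                    "chrom1": np.asarray(layout.names, dtype=object)[c1],
                    "pos1": pos1,
                    "chrom2": np.asarray(layout.names, dtype=object)[c2],
                    "pos2": pos2,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["strand1"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    df["strand2"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    if n_dup:
        dup_idx = rng.choice(len(df), size=n_dup, replace=True)
        df = pd.concat([df, df.iloc[dup_idx]], ignore_index=True)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "read_id", [f"read{i}" for i in range(len(df))])
    df = df[PAIRS_COLUMNS]
    pairs = PairsTable(df, layout)
    bt = BinTable(layout, spec.resolution)
    truth = GroundTruth(
        spec.compartment_states,
        None,
        None,
        spec.alpha,
        spec.bias,
        float(n_cis),
        float(n_trans),
        float(n),
    )
    return pairs, truth


def spec_from_config(config: dict) -> SyntheticSpec:
    """Build a SyntheticSpec from a plain (e.g. YAML-loaded) mapping."""
    layout = GenomeLayout(
        tuple(config["chromosomes"].keys()),
        tuple(int(v) for v in config["chromosomes"].values()),
    )
    bt = BinTable(layout, int(config["resolution"]))
    states = None
    if "compartment_block_bins" in config:
        block = int(config["compartment_block_bins"])
        states = np.empty(bt.n_bins)
        for chrom in layout.names:
            sl = bt.chrom_slice(chrom)
            idx = np.arange(sl.stop - sl.start)
            states[sl] = np.where((idx // block) % 2 == 0, 1.0, -1.0)
    loops = []
    for item in config.get("loops", []):
        chrom, a1, a2 = item["chrom"], int(item["anchor1"]), int(item["anchor2"])
        res = int(config["resolution"])
        loops.append(
            (
                Region(chrom, a1 - a1 % res, a1 - a1 % res + res),
                Region(chrom, a2 - a2 % res, a2 - a2 % res + res),
            )
        )
    return SyntheticSpec(
        layout=layout,
        resolution=int(config["resolution"]),
        n_contacts=int(config["n_contacts"]),
        alpha=float(config.get("alpha", 1.0)),
        s_min=config.get("s_min"),
        s_max=config.get("s_max"),
        cis_fraction=float(config.get("cis_fraction", 0.9)),
        compartment_states=states,
        plaid_strength=float(config.get("plaid_strength", 0.0)),
        domain_boundaries={
            k: list(v) for k, v in config.get("domain_boundaries", {}).items()
        },
        domain_multiplier=float(config.get("domain_multiplier", 1.0)),
        loops=loops,
        loop_enrichment=float(config.get("loop_enrichment", 1.0)),
        duplicate_rate=float(config.get("duplicate_rate", 0.0)),
        seed=int(config.get("seed", 0)),
    )
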