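"""Shared fixtures: small toy maps plus seeded synthetic study fixtures."""

import numpy as np
import pytest

import hicmap as hm
from hicmap.synthetic import SyntheticSpec


def toy_map(counts, resolution=1000, chrom="chrI", extra_layers=None):
    """Build a single-chromosome ContactMap from a dense symmetric array."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    layout = hm.GenomeLayout((chrom,), (n * resolution,))
    bt = hm.BinTable(layout, resolution)
    iu = np.triu_indices(n)
    vals = counts[iu]
    keep = vals != 0
    scores = {"count": vals[keep].astype(np.int64)}
    if extra_layers:
        for name, mat in extra_layers.items():
            scores[name] = np.asarray(mat)[iu][keep]
    ints = hm.InteractionSet(iu[0][keep], iu[1][keep], scores, canonical=True)
    return hm.ContactMap(bt, ints)


@pytest.fixture(scope="session")
def two_chrom_layout():
    return hm.GenomeLayout(("chrI", "chrII"), (100_000, 60_000))


@pytest.fixture(scope="session")
def small_map(two_chrom_layout):
    """2-chromosome 1 kb map, moderate depth, with a short last bin."""
    spec = SyntheticSpec(
        two_chrom_layout, 1000, 50_000, alpha=1.0, cis_fraction=0.9, seed=11
    )
    cmap, truth = hm.synthesize_map(spec)
    return cmap, truth


@pytest.fixture(scope="session")
def balanced_small_map(small_map):
    cmap, _ = small_map
    out, result = hm.balance(cmap)
    return out, result


@pytest.fixture(scope="session")
def plaid_map():
    """Plaid fixture: gamma=0.4, 20-bin alternating blocks, depth 1e6."""
    layout = hm.GenomeLayout(("chrI",), (4_000_000,))
    res = 10_000
    n = 400
    states = np.where((np.arange(n) // 20) % 2 == 0, 1.0, -1.0)
    spec = SyntheticSpec(
        layout,
        res,
        1_000_000,
        alpha=1.0,
        cis_fraction=1.0,
        compartment_states=states,
        plaid_strength=0.4,
        seed=21,
    )
    cmap, truth = hm.synthesize_map(spec)
    return cmap, truth


@pytest.fixture(scope="session")
def plaid_detrended(plaid_map):
    cmap, truth = plaid_map
    balanced, _ = hm.balance(cmap)
    return hm.detrend(balanced), truth


@pytest.fixture(scope="session")
def domain_map():
    """8 planted TAD boundaries, delta=3, on a plain decay background."""
    layout = hm.GenomeLayout(("chrI",), (540_000,))
    res = 2000
    cuts = [60_000 * k for k in range(1, 9)]  # 8 boundaries, 30-bin domains
    spec = SyntheticSpec(
        layout,
        res,
        800_000,
        alpha=1.0,
        cis_fraction=1.0,
        domain_boundaries={"chrI": cuts},
        domain_multiplier=3.0,
        seed=31,
    )
    cmap, truth = hm.synthesize_map(spec)
    return cmap, truth


@pytest.fixture(scope="session")
def loop_map():
    """20 planted loops at 5x enrichment on a deep decay background."""
    layout = hm.GenomeLayout(("chrI",), (800_000,))
    res = 2000
    rng = np.random.default_rng(41)
    loops = []
    taken = []
    while len(loops) < 20:
        i = int(rng.integers(10, 360))
        j = i + int(rng.integers(8, 50))
        if j >= 390:
            continue
        if any(max(abs(i - a), abs(j - b)) < 6 for a, b in taken):
            continue
        taken.append((i, j))
        loops.append(
            (
                hm.Region("chrI", i * res, (i + 1) * res),
                hm.Region("chrI", j * res, (j + 1) * res),
            )
        )
    spec = SyntheticSpec(
        layout,
        res,
        3_000_000,
        alpha=1.0,
        cis_fraction=1.0,
        loops=loops,
        loop_enrichment=5.0,
        seed=42,
    )
    cmap, truth = hm.synthesize_map(spec)
    return cmap, truth
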