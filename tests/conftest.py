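import numpy as np
import pandas as pd
import pytest

from fragpop import synthetic as syn
from fragpop.core_data import CoverRaster, DetectionData, GenotypeTable


@pytest.fixture(scope="session")
def hwe_genotypes() -> GenotypeTable:
    """Large HWE population (no inbreeding, no structure)."""
    cfg = syn.PopSimConfig(
        n_individuals=300,
        allele_freqs=syn.default_allele_freqs(10, 6, seed=21),
        f_is=0.0,
        seed=22,
    )
    return syn.simulate_genotypes(cfg)


@pytest.fixture()
def small_gt() -> GenotypeTable:
    """Hand-built 4-individual, 3-locus table with one missing pair."""
    calls = np.array(
        [
            [[120, 124], [100, 100], [90, 92]],
            [[120, 120], [100, 102], [0, 0]],
            [[124, 124], [102, 102], [90, 90]],
            [[120, 124], [100, 102], [92, 92]],
        ]
    )
    return GenotypeTable(
        ["a", "b", "c", "d"],
        ["F", "M", "F", "M"],
        ["p1"] * 4,
        ["LA", "LB", "LC"],
        calls,
    )


@pytest.fixture()
def tiny_detections() -> DetectionData:
    """Two traps, one session, three occasions, two individuals."""
    traps = pd.DataFrame(
        {"trap_id": ["T1", "T2"], "x": [0.0, 1.0], "y": [0.0, 0.0]}
    )
    y = np.zeros((2, 2, 3), dtype=int)
    y[0, 0, 0] = 1  # ind a at T1 occ1
    y[0, 0, 2] = 1  # ind a at T1 occ3 (post-bk)
    y[1, 1, 1] = 1  # ind b at T2 occ2
    return DetectionData(
        ["S1"], {"S1": traps}, {"S1": 3}, {"S1": y},
        {"S1": ["a", "b"]}, {"a": "F", "b": "M"},
    )


@pytest.fixture(scope="session")
def frag_raster() -> CoverRaster:
    """Seeded fragmented landscape at the study's percent habitat."""
    return syn.simulate_landscape(syn.LandscapeConfig(seed=7))


def random_genotype_table(seed: int, n: int = 12, L: int = 5) -> GenotypeTable:
    """Arbitrary valid genotype table for round-trip properties."""
    rng = np.random.default_rng(seed)
    calls = rng.integers(100, 140, size=(n, L, 2))
    missing = rng.random((n, L)) < 0.1
    calls[missing] = 0
    return GenotypeTable(
        [f"i{k}" for k in range(n)],
        list(rng.choice(["M", "F"], size=n)),
        list(rng.choice(["p1", "p2"], size=n)),
        [f"L{j}" for j in range(L)],
        calls,
    )
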