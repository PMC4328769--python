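import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radscape.catalog import LocusCatalog
from radscape.io import PopulationMap

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def build_catalog(
    geno_by_locus: list[np.ndarray],
    individuals: list[str],
    popmap: PopulationMap | None = None,
    depth: int = 20,
    locus_length: int = 100,
    depths: np.ndarray | None = None,
) -> LocusCatalog:
    """Assemble a catalog from per-locus (n_snps, n_ind, 2) genotype blocks."""
    n = len(individuals)
    m = len(geno_by_locus)
    snp_locus, snp_pos, blocks = [], [], []
    for li, block in enumerate(geno_by_locus):
        block = np.asarray(block, dtype=np.int8)
        for p in range(block.shape[0]):
            snp_locus.append(li)
            snp_pos.append(p)
        if block.shape[0]:
            blocks.append(block)
    geno = np.concatenate(blocks, axis=0) if blocks else np.empty((0, n, 2), np.int8)
    if depths is None:
        depths = np.full((m, n), depth, dtype=np.int64)
    called = np.ones((m, n), dtype=bool)
    # derive called from the first SNP of each locus when genotypes are missing
    idx = 0
    for li, block in enumerate(geno_by_locus):
        if np.asarray(block).shape[0]:
            called[li] = np.asarray(block)[0, :, 0] >= 0
        idx += np.asarray(block).shape[0]
    return LocusCatalog(
        individuals=individuals,
        locus_ids=[f"L{i:04d}" for i in range(m)],
        locus_lengths=np.full(m, locus_length, dtype=np.int64),
        snp_locus=np.asarray(snp_locus, dtype=np.int64),
        snp_pos=np.asarray(snp_pos, dtype=np.int64),
        geno=geno,
        depth=depths,
        called=called,
        popmap=popmap,
    )


@pytest.fixture
def two_region_popmap() -> PopulationMap:
    inds = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    return PopulationMap(inds, {i: f"{i[0]}-s1" for i in inds}, {i: i[0] for i in inds})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
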