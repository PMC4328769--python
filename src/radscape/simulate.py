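"""Coalescent-based synthetic data: RAD catalogs and mitochondrial alignments.

Genealogies are drawn with msprime under a divergence `Scenario`; mutations
are dropped with a finite-sites 4-state (Jukes-Cantor) model restricted to
the variable fraction of each locus.  A locus of length L with invariant
fraction f exposes round(L*(1-f)) mutable sites, which implements the
"98 % invariant for 100-bp RAD stacks / 95 % for the 658-bp mitochondrial
fragment" convention and bounds the number of SNPs per RAD locus at 2.

Effective-size convention: `Scenario.sizes` are diploid (nuclear) effective
sizes N.  Nuclear loci coalesce at rate 1/(2N) per lineage pair; the
mitochondrial genome carries a fourfold smaller effective number of gene
copies, implemented by scaling every population size by 1/4 (pair rate
2/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import msprime
import numpy as np

from .catalog import LocusCatalog, mask_low_depth
from .errors import ConfigurationError
from .io import HaplotypeAlignment, PopulationMap
from .scenarios import Scenario

#: nucleotide frequencies reported for the study's RAD alignment; used for
#: the invariant backbone of simulated sequences
DEFAULT_BASE_FREQS = (0.269, 0.228, 0.225, 0.278)  # A, C, G, T

MITO_SIZE_SCALE = 0.25


def _msp_seed(seed: int) -> int:
    return int(seed) % (2**31 - 2) + 1


@dataclass(frozen=True)
class SampleDesign:
    """Sampling design for one marker.

    `samples` maps region -> number of haploid lineages sampled.  RAD loci
    are diploid, so RAD counts must be even (2 per individual); the
    mitochondrial marker contributes one lineage per individual.
    """

    marker: str
    samples: dict[str, int] = field(hash=False)
    n_loci: int = 1
    locus_length: int = 100
    mutation_rate: float = 1e-7
    invariant_fraction: float = 0.98
    sites_per_region: dict[str, int] | None = field(default=None, hash=False)
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS

    def __post_init__(self) -> None:
        if self.marker not in ("rad", "mito"):
            raise ConfigurationError(f"unknown marker {self.marker!r}")
        if not 0.0 <= self.invariant_fraction <= 1.0:
            raise ConfigurationError("invariant_fraction must lie in [0, 1]")
        for r, n in self.samples.items():
            if n <= 0:
                raise ConfigurationError(f"non-positive sample count for {r!r}")
            if self.marker == "rad" and n % 2:
                raise ConfigurationError(
                    f"RAD samples are diploid: count for {r!r} must be even"
                )
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ConfigurationError("base frequencies must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SampleDesign":
        """Build a design from a JSON-style mapping (keys = field names)."""
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
        if "base_freqs" in d:
            d = {**d, "base_freqs": tuple(d["base_freqs"])}
        return cls(**d)

    @property
    def ploidy(self) -> int:
        return 2 if self.marker == "rad" else 1

    @property
    def n_individuals(self) -> int:
        return sum(self.samples.values()) // self.ploidy

    @property
    def n_variable_sites(self) -> int:
        return int(round(self.locus_length * (1.0 - self.invariant_fraction)))

    def individual_names(self) -> list[str]:
        tag = "" if self.marker == "rad" else "m"
        names = []
        for r, n in self.samples.items():
            for i in range(n // self.ploidy):
                names.append(f"{r}{tag}{i + 1:03d}")
        return names

    def popmap(self) -> PopulationMap:
        names = self.individual_names()
        spr = self.sites_per_region or {r: 1 for r in self.samples}
        sites, regions = {}, {}
        i = 0
        for r, n in self.samples.items():
            k = spr.get(r, 1)
            for j in range(n // self.ploidy):
                sites[names[i]] = f"{r}-s{j % k + 1}"
                regions[names[i]] = r
                i += 1
        return PopulationMap(names, sites, regions)


def rad_study_design(n_loci: int = 12_514) -> SampleDesign:
    """The study's RAD design: 17 diploid individuals in 8 sites, 4 regions."""
    return SampleDesign(
        marker="rad",
        samples={"BF": 20, "MC": 4, "PY": 4, "CM": 6},
        n_loci=n_loci,
        locus_length=100,
        mutation_rate=1e-7,
        invariant_fraction=0.98,
        sites_per_region={"BF": 3, "MC": 1, "PY": 2, "CM": 2},
    )


def mito_study_design() -> SampleDesign:
    """The study's CO1 design: 352 haploid sequences in 26 sites, 4 regions."""
    return SampleDesign(
        marker="mito",
        samples={"BF": 219, "MC": 7, "PY": 61, "CM": 65},
        n_loci=1,
        locus_length=658,
        mutation_rate=1e-6,
        invariant_fraction=0.95,
        sites_per_region={"BF": 13, "MC": 1, "PY": 5, "CM": 7},
    )


@dataclass
class GeneTree:
    """A rooted genealogy of the sampled lineages at one locus."""

    ts: "msprime.TreeSequence"
    sample_regions: list[str]
    design: SampleDesign
    scenario: Scenario

    @property
    def n_samples(self) -> int:
        return len(self.sample_regions)

    def newick(self) -> str:
        return self.ts.first().newick()

    def tmrca(self) -> float:
        tree = self.ts.first()
        return tree.time(tree.root)

    def min_cross_region_height(self) -> float:
        """Height of the lowest node whose subtree spans several regions."""
        tree = self.ts.first()
        best = np.inf
        for node in tree.nodes():
            if tree.is_leaf(node):
                continue
            regions = {self.sample_regions[leaf] for leaf in tree.leaves(node)}
            if len(regions) > 1:
                best = min(best, tree.time(node))
        return best


def _sample_sets(scenario: Scenario, design: SampleDesign) -> list[msprime.SampleSet]:
    sets = []
    for r, n in design.samples.items():
        if r not in scenario.leaves:
            raise ConfigurationError(f"region {r!r} sampled but absent from scenario")
        n_units = n // design.ploidy
        sets.append(msprime.SampleSet(n_units, population=r, ploidy=design.ploidy))
    return sets


def _size_scale(design: SampleDesign) -> float:
    return MITO_SIZE_SCALE if design.marker == "mito" else 1.0


def draw_coalescent_tree(
    scenario: Scenario, design: SampleDesign, rng_seed: int
) -> GeneTree:
    """Draw one genealogy for the design's samples under the scenario.

    Within a region holding k lineages the coalescence rate is
    C(k,2)/(2*N_e) per generation for nuclear loci (N_e/4 in place of N_e
    for the mitochondrial marker); lineages in different regions cannot
    coalesce before the regions' merge time.
    """
    demog = scenario.demography(size_scale=_size_scale(design))
    n_var = design.n_variable_sites
    ts = msprime.sim_ancestry(
        samples=_sample_sets(scenario, design),
        demography=demog,
        sequence_length=max(n_var, 1),
        discrete_genome=True,
        ploidy=2,
        random_seed=_msp_seed(rng_seed),
        record_provenance=False,
    )
    regions = []
    for r, n in design.samples.items():
        regions.extend([r] * n)
    return GeneTree(ts, regions, design, scenario)


@dataclass
class LocusHaplotypes:
    """One simulated sequence per sampled lineage at a single locus."""

    matrix: np.ndarray  # (n_samples, L) int8 codes
    snp_positions: np.ndarray  # positions of segregating sites within locus
    snp_matrix: np.ndarray  # (n_snps, n_samples) int8 codes
    sample_regions: list[str]

    def sequences(self) -> list[str]:
        from .io import codes_to_seq

        return [codes_to_seq(row) for row in self.matrix]


def _variant_sites(mts) -> tuple[np.ndarray, np.ndarray]:
    """Segregating site positions and code matrix (sites x samples)."""
    positions, rows = [], []
    code_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    for var in mts.variants():
        codes = np.array([code_of[a] for a in var.alleles if a is not None], dtype=np.int8)
        row = codes[var.genotypes]
        if len(np.unique(row)) < 2:
            continue  # back-mutation restored monomorphism
        positions.append(int(var.site.position))
        rows.append(row)
    if not rows:
        n = mts.num_samples
        return np.empty(0, dtype=np.int64), np.empty((0, n), dtype=np.int8)
    return np.asarray(positions, dtype=np.int64), np.vstack(rows)


def mutate_locus(tree: GeneTree, design: SampleDesign, rng_seed: int) -> LocusHaplotypes:
    """Drop finite-sites JC mutations on a genealogy and emit sequences.

    The expected mutation count is mu * total branch length * L_variable
    where L_variable = round(locus_length * (1 - invariant_fraction));
    invariant sites take their state from the design's base frequencies.
    """
    rng = np.random.default_rng(rng_seed)
    n_var = design.n_variable_sites
    L = design.locus_length
    n = tree.n_samples

    ancestral = rng.choice(4, size=L, p=np.asarray(design.base_freqs)).astype(np.int8)
    matrix = np.tile(ancestral, (n, 1))

    if n_var == 0 or design.mutation_rate == 0.0:
        return LocusHaplotypes(
            matrix,
            np.empty(0, dtype=np.int64),
            np.empty((0, n), dtype=np.int8),
            list(tree.sample_regions),
        )

    mts = msprime.sim_mutations(
        tree.ts,
        rate=design.mutation_rate,
        model=msprime.JC69(),
        random_seed=_msp_seed(rng_seed),
        record_provenance=False,
    )
    var_pos, var_mat = _variant_sites(mts)
    site_map = np.sort(rng.choice(L, size=n_var, replace=False))
    snp_positions = site_map[var_pos]
    matrix[:, snp_positions] = var_mat.T
    return LocusHaplotypes(matrix, snp_positions, var_mat, list(tree.sample_regions))


def simulate_marker(
    scenario: Scenario,
    design: SampleDesign,
    rng_seed: int,
    default_depth: int = 20,
):
    """Simulate a full dataset for one marker.

    Returns a LocusCatalog for marker="rad" (loci are unlinked: one
    independent genealogy each; the two lineages of an individual form its
    genotype) or a HaplotypeAlignment for marker="mito".
    """
    demog = scenario.demography(size_scale=_size_scale(design))
    n_var = design.n_variable_sites
    popmap = design.popmap()
    names = popmap.individuals

    ss = np.random.SeedSequence(rng_seed)
    anc_seed, mut_base = (int(x) for x in ss.generate_state(2, dtype=np.uint32))
    mut_seeds = np.random.SeedSequence(mut_base).generate_state(design.n_loci, dtype=np.uint32)

    replicates = msprime.sim_ancestry(
        samples=_sample_sets(scenario, design),
        demography=demog,
        sequence_length=max(n_var, 1),
        discrete_genome=True,
        ploidy=2,
        num_replicates=design.n_loci,
        random_seed=_msp_seed(anc_seed),
        record_provenance=False,
    )

    all_pos: list[np.ndarray] = []
    all_mats: list[np.ndarray] = []
    locus_of: list[int] = []
    for li, ts in enumerate(replicates):
        if n_var == 0 or design.mutation_rate == 0.0:
            continue
        mts = msprime.sim_mutations(
            ts,
            rate=design.mutation_rate,
            model=msprime.JC69(),
            random_seed=_msp_seed(int(mut_seeds[li])),
            record_provenance=False,
        )
        pos, mat = _variant_sites(mts)
        if len(pos):
            all_pos.append(pos)
            all_mats.append(mat)
            locus_of.extend([li] * len(pos))

    n_snps = len(locus_of)
    n_samples = sum(design.samples.values())
    if n_snps:
        snp_pos = np.concatenate(all_pos)
        snp_mat = np.vstack(all_mats)
    else:
        snp_pos = np.empty(0, dtype=np.int64)
        snp_mat = np.empty((0, n_samples), dtype=np.int8)
    snp_locus = np.asarray(locus_of, dtype=np.int64)

    if design.marker == "mito":
        rng = np.random.default_rng(anc_seed)
        ancestral = rng.choice(4, size=design.locus_length, p=np.asarray(design.base_freqs))
        codes = np.tile(ancestral.astype(np.int8), (n_samples, 1))
        if n_snps:
            site_map = np.sort(rng.choice(design.locus_length, size=n_var, replace=False))
            codes[:, site_map[snp_pos]] = snp_mat.T
        return HaplotypeAlignment(names, codes, popmap)

    n_ind = design.n_individuals
    geno = np.empty((n_snps, n_ind, 2), dtype=np.int8)
    geno[:, :, 0] = snp_mat[:, 0::2]
    geno[:, :, 1] = snp_mat[:, 1::2]
    return LocusCatalog(
        individuals=names,
        locus_ids=[f"L{li:06d}" for li in range(design.n_loci)],
        locus_lengths=np.full(design.n_loci, design.locus_length, dtype=np.int64),
        snp_locus=snp_locus,
        snp_pos=snp_pos,
        geno=geno,
        depth=np.full((design.n_loci, n_ind), default_depth, dtype=np.int64),
        called=np.ones((design.n_loci, n_ind), dtype=bool),
        popmap=popmap,
    )


def simulate_dataset(
    scenario: Scenario,
    rad_design: SampleDesign,
    mito_design: SampleDesign,
    rng_seed: int,
) -> tuple[LocusCatalog, HaplotypeAlignment]:
    """Simulate both markers under one scenario (independent genealogies)."""
    s_rad, s_mito = np.random.SeedSequence(rng_seed).generate_state(2, dtype=np.uint32)
    catalog = simulate_marker(scenario, rad_design, int(s_rad))
    alignment = simulate_marker(scenario, mito_design, int(s_mito))
    return catalog, alignment


@dataclass(frozen=True)
class ObservationModel:
    """Per-genotype read-depth model used to impose realistic missingness.

    Depths are negative-binomial with the given mean and dispersion
    (variance = mean + mean^2/dispersion); an optional lognormal locus
    effect (sd on the log scale) makes some loci systematically shallow.
    Genotypes below `min_depth` are masked.  `constant_depth` short-circuits
    the draw (useful for forcing edge cases).
    """

    mean_depth: float = 20.0
    dispersion: float = 3.0
    min_depth: int = 5
    locus_effect_sd: float = 0.0
    constant_depth: int | None = None

    def masked_fraction(self) -> float:
        """P(depth < min_depth) under the plain negative binomial."""
        from scipy import stats as sps

        k, m = self.dispersion, self.mean_depth
        return float(sps.nbinom.cdf(self.min_depth - 1, k, k / (k + m)))


def apply_observation_model(
    catalog: LocusCatalog, model: ObservationModel, rng_seed: int
) -> LocusCatalog:
    """Draw depths and mask genotypes below the depth floor."""
    rng = np.random.default_rng(rng_seed)
    shape = catalog.depth.shape
    if model.constant_depth is not None:
        depth = np.full(shape, model.constant_depth, dtype=np.int64)
    else:
        mean = np.full(shape, model.mean_depth)
        if model.locus_effect_sd > 0:
            sd = model.locus_effect_sd
            effect = rng.lognormal(-0.5 * sd**2, sd, size=shape[0])
            mean = mean * effect[:, None]
        k = model.dispersion
        depth = rng.negative_binomial(k, k / (k + mean)).astype(np.int64)
    out = _dc_replace(catalog, depth=depth)
    if model.min_depth > 0:
        out = mask_low_depth(out, model.min_depth)
    return out


def planted_het_catalog(
    rates: dict[str, float] | None = None,
    n_loci: int = 2000,
    samples: dict[str, int] | None = None,
    locus_length: int = 100,
    depth: int = 20,
    rng_seed: int = 0,
) -> LocusCatalog:
    """Catalog with planted per-SNP heterozygosity rates per region.

    Default rates are the study's reported region means (BF 2.5-2.6 %,
    MC 11.4 %, PY 3.5 %, CM 14.5 % at the individual extremes); each locus
    carries one SNP and each genotype is heterozygous with its region's
    rate, independently across loci.
    """
    rates = rates or {"BF": 0.026, "MC": 0.114, "PY": 0.035, "CM": 0.145}
    samples = samples or {"BF": 20, "MC": 4, "PY": 4, "CM": 6}
    design = SampleDesign(marker="rad", samples=samples, n_loci=n_loci,
                          locus_length=locus_length)
    popmap = design.popmap()
    names = popmap.individuals
    n_ind = len(names)
    rate_vec = np.array([rates[popmap.region_of(i)] for i in names])

    rng = np.random.default_rng(rng_seed)
    het = rng.random((n_loci, n_ind)) < rate_vec[None, :]
    geno = np.zeros((n_loci, n_ind, 2), dtype=np.int8)
    geno[:, :, 1] = het.astype(np.int8)  # het -> (A, C), hom -> (A, A)
    return LocusCatalog(
        individuals=names,
        locus_ids=[f"P{li:06d}" for li in range(n_loci)],
        locus_lengths=np.full(n_loci, locus_length, dtype=np.int64),
        snp_locus=np.arange(n_loci, dtype=np.int64),
        snp_pos=np.zeros(n_loci, dtype=np.int64),
        geno=geno,
        depth=np.full((n_loci, n_ind), depth, dtype=np.int64),
        called=np.ones((n_loci, n_ind), dtype=bool),
        popmap=popmap,
    )
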