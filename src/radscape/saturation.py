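"""Locus-subsampling convergence diagnostics.

Two procedures ask how many RAD loci are enough:

- heterozygosity saturation: redraw L loci many times and track the mean
  and SD of heterozygosity per region (or per tracked individual) as L
  grows; convergence is read off the mean +/- SD bands;
- topology saturation: redraw L loci, concatenate their SNP columns into
  one pseudo-haplotype per individual, build a neighbor-joining tree from
  Kimura-2-parameter distances and measure the rescaled Robinson-Foulds
  distance to a constraint tree; the convergence point is the smallest L
  from which the mean distance stays below a threshold (default 0.025).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import LocusCatalog
from .errors import ConfigurationError, DegenerateInputError
from .io import PopulationMap
from .stats import k2p_matrix
from .trees import ConstraintTree, Tree, nj_tree, rescaled_rf


@dataclass
class SaturationCurve:
    """Replicate values of a statistic indexed by number of subsampled loci."""

    grid: np.ndarray
    values: dict[str, np.ndarray]  # unit -> (len(grid), reps)
    seed: int
    convergence: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if np.any(np.diff(self.grid) <= 0):
            raise ConfigurationError("grid must be strictly increasing")

    def mean(self, unit: str) -> np.ndarray:
        return np.nanmean(self.values[unit], axis=1)

    def sd(self, unit: str) -> np.ndarray:
        return np.nanstd(self.values[unit], axis=1, ddof=1)

    def band(self, unit: str) -> tuple[np.ndarray, np.ndarray]:
        m, s = self.mean(unit), self.sd(unit)
        return m - s, m + s

    def to_frame(self):
        import pandas as pd

        rows = []
        for unit in self.values:
            m, s = self.mean(unit), self.sd(unit)
            for gi, L in enumerate(self.grid):
                rows.append({"unit": unit, "n_loci": int(L), "mean": m[gi], "sd": s[gi]})
        return pd.DataFrame(rows)


def subsample_loci(catalog: LocusCatalog, n: int, rng_seed: int) -> LocusCatalog:
    """Uniform sample of `n` loci without replacement (deterministic per seed)."""
    if n > catalog.n_loci:
        raise ConfigurationError(f"cannot draw {n} of {catalog.n_loci} loci")
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(catalog.n_loci, size=n, replace=False))
    return catalog.subset_loci(idx)


def _het_count_matrices(catalog: LocusCatalog) -> tuple[np.ndarray, np.ndarray]:
    """Per (locus, individual) heterozygous and called SNP counts."""
    het = catalog.snp_het().astype(np.int64)
    called = catalog.snp_called().astype(np.int64)
    m, n = catalog.n_loci, catalog.n_individuals
    H = np.zeros((m, n), dtype=np.int64)
    C = np.zeros((m, n), dtype=np.int64)
    np.add.at(H, catalog.snp_locus, het)
    np.add.at(C, catalog.snp_locus, called)
    return H, C


def _bands_separated(curve: SaturationCurve, unit_a: str, unit_b: str) -> int | None:
    """Smallest grid L from which the two units' mean +/- SD bands stay
    disjoint at every subsequent grid point; None if they never do."""
    lo_a, hi_a = curve.band(unit_a)
    lo_b, hi_b = curve.band(unit_b)
    disjoint = (hi_a < lo_b) | (hi_b < lo_a)
    for gi in range(len(curve.grid)):
        if disjoint[gi:].all():
            return int(curve.grid[gi])
    return None


def het_saturation(
    catalog: LocusCatalog,
    popmap: PopulationMap | None = None,
    grid: np.ndarray | None = None,
    reps: int = 1000,
    level: str = "region",
    rng_seed: int = 0,
    track: list[str] | None = None,
    sd_fraction: float = 0.1,
) -> SaturationCurve:
    """Heterozygosity saturation curves over locus subsamples.

    level="region" tracks region means (default 1000 replicates);
    level="individual" tracks individual heterozygosities (the study used
    100 replicates for its two extreme individuals; pass them via `track`).
    The convergence entry holds, for regions, the smallest L from which
    every tracked region's replicate SD stays below `sd_fraction` of its
    mean, and for a tracked individual pair, the smallest L from which
    their mean +/- SD bands stay disjoint.
    """
    popmap = popmap or catalog.popmap
    if popmap is None:
        raise ConfigurationError("no population map available")
    if grid is None:
        grid = np.arange(10, 1001, 10)
    grid = np.asarray(grid, dtype=np.int64)
    if grid[-1] > catalog.n_loci:
        raise ConfigurationError("grid exceeds the number of loci")
    if level == "region" and reps == 1000:
        pass
    elif level == "individual" and reps == 1000:
        reps = 100

    H, C = _het_count_matrices(catalog)
    if level == "region":
        units = track or popmap.region_labels
        member_idx = {
            r: [catalog.individuals.index(i) for i in popmap.members(r)] for r in units
        }
        if any(not v for v in member_idx.values()):
            raise ConfigurationError("empty region in popmap")
    elif level == "individual":
        units = track or list(catalog.individuals)
        col = {u: catalog.individuals.index(u) for u in units}
    else:
        raise ConfigurationError(f"unknown saturation level {level!r}")

    rng = np.random.default_rng(rng_seed)
    values = {u: np.full((len(grid), reps), np.nan) for u in units}
    for rep in range(reps):
        perm = rng.permutation(catalog.n_loci)
        for gi, L in enumerate(grid):
            idx = perm[:L]
            h = H[idx].sum(axis=0)
            c = C[idx].sum(axis=0)
            with np.errstate(invalid="ignore"):
                ind_het = np.where(c > 0, h / np.maximum(c, 1), np.nan)
            if level == "individual":
                for u in units:
                    values[u][gi, rep] = ind_het[col[u]]
            else:
                for u in units:
                    values[u][gi, rep] = np.nanmean(ind_het[member_idx[u]])

    curve = SaturationCurve(grid, values, rng_seed)
    if level == "individual" and len(units) == 2:
        curve.convergence["band_separation_L"] = _bands_separated(curve, *units)
    if level == "region":
        ok = np.ones(len(grid), dtype=bool)
        for u in units:
            m, s = curve.mean(u), curve.sd(u)
            with np.errstate(invalid="ignore"):
                ok &= s <= sd_fraction * np.abs(m)
        conv = None
        for gi in range(len(grid)):
            if ok[gi:].all():
                conv = int(grid[gi])
                break
        curve.convergence["sd_stable_L"] = conv
    return curve


def pseudo_haplotypes(catalog: LocusCatalog) -> np.ndarray:
    """(n_individuals, n_snps) code matrix, one sequence per individual.

    Heterozygous genotypes are resolved to the site's major allele (a
    documented simplification); missing genotypes stay -1.
    """
    geno = catalog.geno
    n_snps = catalog.n_snps
    major = np.zeros(n_snps, dtype=np.int8)
    flat = geno.reshape(n_snps, -1)
    counts = np.stack([(flat == a).sum(axis=1) for a in range(4)], axis=1)
    major = np.argmax(counts, axis=1).astype(np.int8)  # argmax ties -> lower code

    out = np.where(
        geno[:, :, 0] < 0,
        np.int8(-1),
        np.where(geno[:, :, 0] != geno[:, :, 1], major[:, None], geno[:, :, 0]),
    ).astype(np.int8)
    return out.T


def topology_saturation(
    catalog: LocusCatalog,
    reference: ConstraintTree,
    popmap: PopulationMap | None = None,
    grid: np.ndarray | None = None,
    reps: int = 100,
    rng_seed: int = 0,
    threshold: float = 0.025,
) -> tuple[SaturationCurve, int | None]:
    """Tree-distance saturation over locus subsamples.

    Per replicate: subsample L loci, build per-individual pseudo-haplotypes
    from the concatenated SNP columns, compute pairwise K2P distances, a
    neighbor-joining tree, and its rescaled Robinson-Foulds distance to the
    reference.  Individuals without data in a subsample are dropped from
    that replicate (the reference is restricted accordingly).  Returns the
    curve plus the smallest grid L whose mean is below `threshold` there
    and at every larger grid point ("constantly below"); None if never.
    """
    if not reference.splits():
        raise DegenerateInputError("reference star tree: rescaled distance undefined")
    if grid is None:
        grid = np.arange(100, 5001, 100)
    grid = np.asarray(grid, dtype=np.int64)
    if grid[-1] > catalog.n_loci:
        raise ConfigurationError("grid exceeds the number of loci")

    rng = np.random.default_rng(rng_seed)
    values = np.full((len(grid), reps), np.nan)
    names = list(catalog.individuals)
    for rep in range(reps):
        perm = rng.permutation(catalog.n_loci)
        for gi, L in enumerate(grid):
            sub = catalog.subset_loci(np.sort(perm[:L]))
            mat = pseudo_haplotypes(sub)
            has_data = (mat >= 0).any(axis=1)
            keep = np.where(has_data)[0]
            kept_names = [names[i] for i in keep]
            if len(keep) < 4:
                continue
            ref = reference if len(keep) == len(names) else reference.restrict(kept_names)
            if not ref.splits():
                continue
            dist = k2p_matrix(mat[keep])
            if not np.all(np.isfinite(dist)):
                continue
            tree = nj_tree(dist, kept_names)
            values[gi, rep] = rescaled_rf(tree, ref)

    curve = SaturationCurve(grid, {"rf": values}, rng_seed)
    mean = curve.mean("rf")
    convergence = None
    for gi in range(len(grid)):
        if np.all(mean[gi:] < threshold):
            convergence = int(grid[gi])
            break
    curve.convergence["rf_below_threshold_L"] = convergence
    return curve, convergence
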