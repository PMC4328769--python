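"""Diversity and differentiation statistics for RAD and mitochondrial data.

Conventions
-----------
- sequences are int8 code matrices (rows = haploid sequences), -1 = missing;
  all pairwise comparisons use pairwise deletion;
- undefined statistics (Tajima's D at S=0, F_ST on monomorphic data, a
  region with n < 2) are reported as NaN sentinels, never raised;
- grouped outputs iterate regions in sorted label order.

The DIYABC-style summary vector holds, for each region, (1) the mean and
(2) variance of pairwise sequence differences, (3) Tajima's D and (4) the
number of segregating sites, and for each unordered region pair, (5) the
mean within-pair diversity w (average of the two within-region means),
(6) the mean between-region differences b, and (7) F_ST — 4*4 + 6*3 = 34
numbers for four regions, in a fixed documented order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .catalog import LocusCatalog
from .errors import ConfigurationError, DegenerateInputError
from .io import HaplotypeAlignment, HaplotypeTable, PopulationMap, seq_to_codes

# --------------------------------------------------------------- distances


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return seq_to_codes(seq)
    return np.asarray(seq, dtype=np.int8)


def p_distance(seq_a, seq_b) -> tuple[int, float]:
    """Uncorrected distance: (substitutions, proportion) over compared sites."""
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ConfigurationError("sequences must be aligned to equal length")
    both = (a >= 0) & (b >= 0)
    n_comp = int(both.sum())
    if n_comp == 0:
        raise DegenerateInputError("no comparable sites between sequences")
    subs = int(np.sum(a[both] != b[both]))
    return subs, subs / n_comp


_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
    _TRANSITION[_i, _j] = True


def k2p_distance(seq_a, seq_b) -> float:
    """Kimura-2-parameter distance; inf when the correction saturates."""
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    both = (a >= 0) & (b >= 0)
    n_comp = int(both.sum())
    if n_comp == 0:
        raise DegenerateInputError("no comparable sites between sequences")
    aa, bb = a[both], b[both]
    diff = aa != bb
    ts = np.sum(diff & _TRANSITION[aa, bb])
    P = ts / n_comp
    Q = (diff.sum() - ts) / n_comp
    inner = (1.0 - 2.0 * P - Q) * math.sqrt(max(1.0 - 2.0 * Q, 0.0))
    if inner <= 0.0:
        return math.inf
    return -0.5 * math.log(inner)


def k2p_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise K2P distances for rows of a code matrix (pairwise deletion)."""
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = k2p_distance(codes[i], codes[j])
    return out


def pairwise_difference_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(diffs, compared) count matrices over all row pairs, pairwise deletion."""
    codes = np.asarray(codes, dtype=np.int8)
    called = codes >= 0
    compared = called.astype(np.int64) @ called.T.astype(np.int64)
    matches = np.zeros_like(compared)
    for a in range(4):
        ia = (codes == a).astype(np.int64)
        matches += ia @ ia.T
    return compared - matches, compared


# ----------------------------------------------------------- heterozygosity


def individual_heterozygosity(
    catalog: LocusCatalog, individual: str, per_locus: bool = False
) -> float:
    """Proportion of called SNP genotypes that are heterozygous.

    With `per_locus`, the per-locus het proportions are averaged instead
    (loci without called SNPs are skipped).
    """
    ii = catalog.individuals.index(individual)
    called = catalog.snp_called()[:, ii]
    if not called.any():
        raise DegenerateInputError(f"{individual!r} has no called SNP genotypes")
    het = catalog.snp_het()[:, ii]
    if not per_locus:
        return float(het.sum() / called.sum())
    vals = []
    for li in range(catalog.n_loci):
        snps = catalog.snp_locus == li
        c = called[snps].sum()
        if c:
            vals.append(het[snps].sum() / c)
    return float(np.mean(vals))


def region_heterozygosity(
    catalog: LocusCatalog, popmap: PopulationMap | None = None, per_locus: bool = False
) -> dict[str, tuple[float, float]]:
    """Per-region (mean, SD) of individual heterozygosity over members."""
    popmap = popmap or catalog.popmap
    if popmap is None:
        raise ConfigurationError("no population map available")
    out = {}
    for region in popmap.region_labels:
        vals = [
            individual_heterozygosity(catalog, ind, per_locus)
            for ind in popmap.members(region)
            if catalog.snp_called()[:, catalog.individuals.index(ind)].any()
        ]
        if vals:
            out[region] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        else:
            out[region] = (math.nan, math.nan)
    return out


# ---------------------------------------------------------------- diversity


def haplotype_diversity(table: HaplotypeTable, region: str | None = None) -> float:
    """Nei's unbiased haplotype diversity H = n/(n-1) * (1 - sum p_i^2)."""
    counts = table.counts(region)
    n = int(counts.sum())
    if n < 2:
        raise DegenerateInputError("haplotype diversity needs n >= 2 sequences")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(alignment, region: str | None = None) -> float:
    """pi: mean pairwise p-distance proportion over all sequence pairs."""
    if isinstance(alignment, HaplotypeAlignment):
        codes = alignment.region_codes(region) if region else alignment.codes
    else:
        codes = np.asarray(alignment, dtype=np.int8)
    n = codes.shape[0]
    if n < 2:
        raise DegenerateInputError("nucleotide diversity needs n >= 2 sequences")
    diffs, compared = pairwise_difference_matrix(codes)
    iu = np.triu_indices(n, 1)
    comp = compared[iu]
    ok = comp > 0
    if not ok.any():
        raise DegenerateInputError("no comparable sites in any pair")
    return float(np.mean(diffs[iu][ok] / comp[ok]))


# ----------------------------------------------------------------- Tajima D


def _complete_sites(codes: np.ndarray) -> np.ndarray:
    return codes[:, np.all(codes >= 0, axis=0)]


def tajimas_d(codes: np.ndarray) -> float:
    """Tajima's (1989) D from fully called sites; NaN when S = 0.

    Sites with any missing call in the sample are dropped, so the
    pi-estimate and S refer to the same site set.
    """
    codes = _complete_sites(np.asarray(codes, dtype=np.int8))
    n = codes.shape[0]
    if n < 3 or codes.shape[1] == 0:
        return math.nan
    seg = np.array([len(np.unique(col)) > 1 for col in codes.T])
    S = int(seg.sum())
    if S == 0:
        return math.nan
    diffs, _ = pairwise_difference_matrix(codes)
    iu = np.triu_indices(n, 1)
    k_hat = float(np.mean(diffs[iu]))

    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (k_hat - S / a1) / math.sqrt(var)


# --------------------------------------------------------------------- F_ST


def _allele_het_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site allele counts, heterozygote-carrier counts, and called-
    individual counts for a (s, n, 2) genotype block."""
    called = geno[:, :, 0] >= 0
    het = called & (geno[:, :, 0] != geno[:, :, 1])
    counts = np.empty((geno.shape[0], 4))
    het_counts = np.empty((geno.shape[0], 4))
    for allele in range(4):
        carries = geno == allele
        counts[:, allele] = carries.sum(axis=(1, 2))
        het_counts[:, allele] = (het & carries.any(axis=2)).sum(axis=1)
    return counts, het_counts, called.sum(axis=1).astype(float)


def wc_fst(catalog: LocusCatalog, region_a: str, region_b: str,
           popmap: PopulationMap | None = None) -> float:
    """Weir-Cockerham theta between two regions, ratio of sums over SNPs
    and alleles (the multi-locus estimator of their 1984 paper)."""
    popmap = popmap or catalog.popmap
    if popmap is None:
        raise ConfigurationError("no population map available")
    idx_a = [catalog.individuals.index(i) for i in popmap.members(region_a)
             if i in catalog.individuals]
    idx_b = [catalog.individuals.index(i) for i in popmap.members(region_b)
             if i in catalog.individuals]
    if not idx_a or not idx_b:
        raise ConfigurationError("both regions must be sampled in the catalog")
    if catalog.n_snps == 0:
        return math.nan
    r = 2
    counts_a, het_a, n_a = _allele_het_counts(catalog.geno[:, idx_a])
    counts_b, het_b, n_b = _allele_het_counts(catalog.geno[:, idx_b])
    ok = (n_a >= 1) & (n_b >= 1)
    if not ok.any():
        return math.nan
    counts_a, het_a, n_a = counts_a[ok], het_a[ok], n_a[ok]
    counts_b, het_b, n_b = counts_b[ok], het_b[ok], n_b[ok]

    n_bar = (n_a + n_b) / r
    nc = (r * n_bar - (n_a**2 + n_b**2) / (r * n_bar)) / (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = counts_a / (2 * n_a)[:, None]
        p_b = counts_b / (2 * n_b)[:, None]
        p_bar = (n_a[:, None] * p_a + n_b[:, None] * p_b) / (r * n_bar)[:, None]
        s2 = (
            n_a[:, None] * (p_a - p_bar) ** 2 + n_b[:, None] * (p_b - p_bar) ** 2
        ) / ((r - 1) * n_bar)[:, None]
        h_bar = (het_a + het_b) / (r * n_bar)[:, None]
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = (n_bar / nc)[:, None] * (
            s2 - (inner - h_bar / 4.0) / (n_bar - 1)[:, None]
        )
        b = (n_bar / (n_bar - 1))[:, None] * (
            inner - ((2 * n_bar - 1) / (4 * n_bar))[:, None] * h_bar
        )
        c = h_bar / 2.0
        valid = (n_bar > 1)[:, None] & np.isfinite(a) & np.isfinite(b)
    num = float(a[valid].sum())
    den = float((a + b + c)[valid].sum())
    if den == 0.0:
        return math.nan
    return num / den


def hudson_fst(codes_a: np.ndarray, codes_b: np.ndarray, unit: str = "site") -> float:
    """Hudson-style F_ST = 1 - Hw/Hb for haploid sequence sets.

    unit="site" compares sequences site-by-site (mean pairwise p-distance);
    unit="haplotype" compares whole-haplotype identity (frequency-based).
    """
    codes_a = np.asarray(codes_a, dtype=np.int8)
    codes_b = np.asarray(codes_b, dtype=np.int8)
    if codes_a.shape[0] < 2 or codes_b.shape[0] < 2:
        return math.nan

    def within(c):
        d, comp = pairwise_difference_matrix(c)
        iu = np.triu_indices(c.shape[0], 1)
        if unit == "haplotype":
            return float(np.mean(d[iu] > 0))
        ok = comp[iu] > 0
        return float(np.mean(d[iu][ok] / comp[iu][ok]))

    def between(ca, cb):
        stacked = np.vstack([ca, cb])
        d, comp = pairwise_difference_matrix(stacked)
        na = ca.shape[0]
        block_d = d[:na, na:]
        block_c = comp[:na, na:]
        if unit == "haplotype":
            return float(np.mean(block_d > 0))
        ok = block_c > 0
        return float(np.mean(block_d[ok] / block_c[ok]))

    hw = 0.5 * (within(codes_a) + within(codes_b))
    hb = between(codes_a, codes_b)
    if hb == 0.0:
        return math.nan
    return 1.0 - hw / hb


def pairwise_fst(
    data, region_a: str, region_b: str,
    popmap: PopulationMap | None = None, estimator: str = "wc",
) -> float:
    """Dispatch to the Weir-Cockerham (diploid catalog) or Hudson
    (haploid alignment) estimator.  Negative estimates are reported as
    computed; monomorphic data yields NaN."""
    if estimator == "wc":
        if not isinstance(data, LocusCatalog):
            raise ConfigurationError("Weir-Cockerham needs a diploid catalog")
        return wc_fst(data, region_a, region_b, popmap)
    if estimator == "hudson":
        if isinstance(data, HaplotypeAlignment):
            pm = popmap or data.popmap
            mask_a = [pm.region_of(l) == region_a for l in data.labels]
            mask_b = [pm.region_of(l) == region_b for l in data.labels]
            return hudson_fst(data.codes[np.array(mask_a)], data.codes[np.array(mask_b)],
                              unit="haplotype")
        raise ConfigurationError("Hudson estimator needs a haploid alignment")
    raise ConfigurationError(f"unknown F_ST estimator {estimator!r}")


def fst_permutation_test(
    data, region_a: str, region_b: str,
    popmap: PopulationMap | None = None, estimator: str = "wc",
    n_permutations: int = 1000, rng_seed: int = 0,
) -> tuple[float, float]:
    """Observed F_ST and a permutation p-value (individuals shuffled
    across the two regions)."""
    popmap = popmap or getattr(data, "popmap", None)
    observed = pairwise_fst(data, region_a, region_b, popmap, estimator)
    members = popmap.members(region_a) + popmap.members(region_b)
    n_a = len(popmap.members(region_a))
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_permutations):
        perm = list(rng.permutation(members))
        regions = dict(popmap.regions)
        for ind in perm[:n_a]:
            regions[ind] = region_a
        for ind in perm[n_a:]:
            regions[ind] = region_b
        pm = PopulationMap(popmap.individuals, popmap.sites, regions)
        val = pairwise_fst(data, region_a, region_b, pm, estimator)
        if not math.isnan(val) and val >= observed:
            hits += 1
    return observed, (hits + 1) / (n_permutations + 1)


# --------------------------------------------------------- summary vector


@dataclass
class SummaryStatVector:
    """Flattened per-region and per-pair statistics with stable ordering."""

    regions: list[str]
    names: list[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _region_rows(data, popmap: PopulationMap) -> dict[str, np.ndarray]:
    """Region -> haploid code matrix (rows restricted to SNP/variable sites)."""
    if isinstance(data, LocusCatalog):
        mat, labels = data.haplotype_matrix()
        out = {}
        for region in popmap.region_labels:
            rows = [i for i, l in enumerate(labels) if popmap.region_of(l) == region]
            out[region] = mat[rows]
        return out
    if isinstance(data, HaplotypeAlignment):
        variable = np.array(
            [len(np.unique(col[col >= 0])) > 1 for col in data.codes.T]
        )
        codes = data.codes[:, variable] if variable.any() else data.codes[:, :0]
        out = {}
        for region in popmap.region_labels:
            rows = [i for i, l in enumerate(data.labels) if popmap.region_of(l) == region]
            out[region] = codes[rows]
        return out
    raise ConfigurationError("summary statistics need a catalog or an alignment")


def summary_stats(data, popmap: PopulationMap | None = None) -> SummaryStatVector:
    """DIYABC-style summary vector (see module docstring for the layout)."""
    popmap = popmap or getattr(data, "popmap", None)
    if popmap is None:
        raise ConfigurationError("no population map available")
    regions = popmap.region_labels
    if len(regions) < 2:
        raise ConfigurationError("summary statistics need >= 2 regions")
    rows = _region_rows(data, popmap)
    is_catalog = isinstance(data, LocusCatalog)

    names: list[str] = []
    values: list[float] = []
    within_mean: dict[str, float] = {}
    for region in regions:
        codes = rows[region]
        n = codes.shape[0]
        if n >= 2:
            diffs, _ = pairwise_difference_matrix(codes)
            iu = np.triu_indices(n, 1)
            pair_d = diffs[iu].astype(float)
            mpd = float(pair_d.mean())
            vpd = float(pair_d.var())
            complete = _complete_sites(codes)
            seg = np.array([len(np.unique(c)) > 1 for c in complete.T]) if complete.shape[1] else np.zeros(0, bool)
            S = float(seg.sum())
            D = tajimas_d(codes)
        else:
            mpd = vpd = S = D = math.nan
        within_mean[region] = mpd
        names += [f"{region}:mpd", f"{region}:varpd", f"{region}:tajd", f"{region}:segsites"]
        values += [mpd, vpd, D, S]

    for ra, rb in itertools.combinations(regions, 2):
        ca, cb = rows[ra], rows[rb]
        if ca.shape[0] and cb.shape[0]:
            stacked = np.vstack([ca, cb])
            diffs, _ = pairwise_difference_matrix(stacked)
            na = ca.shape[0]
            b = float(diffs[:na, na:].mean())
        else:
            b = math.nan
        w = float(np.nanmean([within_mean[ra], within_mean[rb]]))
        if is_catalog:
            fst = wc_fst(data, ra, rb, popmap)
        else:
            fst = hudson_fst(ca, cb, unit="haplotype")
        names += [f"{ra}-{rb}:w", f"{ra}-{rb}:b", f"{ra}-{rb}:fst"]
        values += [w, b, fst]

    return SummaryStatVector(regions, names, np.asarray(values, dtype=float))


# ------------------------------------------------------------- clock


def strict_clock_time(p_distance_percent: float, rate_percent_per_my: float = 3.54) -> float:
    """Divergence time in My under a strict clock.

    The rate is the between-lineage divergence accumulated per million
    years (3.54 %/My is the arthropod mitochondrial standard), so
    T = distance / rate.
    """
    if rate_percent_per_my <= 0:
        raise ConfigurationError("clock rate must be positive")
    if p_distance_percent < 0:
        raise ConfigurationError("distance must be non-negative")
    return p_distance_percent / rate_percent_per_my
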