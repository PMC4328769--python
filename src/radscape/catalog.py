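"""RAD locus catalog: container, TSV dialect, filtering, and exports.

A catalog holds short unlinked loci genotyped in a fixed panel of diploid
individuals.  Read depth is tracked per locus x individual (all SNPs of a
locus share one stack of reads for an individual), and an individual is
either fully called or fully missing at a locus.

Filtering follows the usual ddRAD hygiene rules: genotypes below a depth
floor are masked, loci with a >2-allele SNP (putative paralogs) or with more
than `max_snps` segregating SNPs are dropped, and loci called in fewer than
`min_individuals` individuals are dropped — in that order.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, EmptyInputError, FormatError
from .io import BASES, PopulationMap, _CODE

_MISSING = -1


@dataclass
class LocusCatalog:
    """Per-individual diploid genotypes at short unlinked loci.

    Attributes
    ----------
    individuals : ordered individual labels (columns)
    locus_ids : (m,) locus identifiers
    locus_lengths : (m,) locus length in bp
    snp_locus : (s,) index into loci for each SNP record
    snp_pos : (s,) 0-based position of the SNP within its locus
    geno : (s, n, 2) int8 base codes, -1 = missing
    depth : (m, n) per locus x individual read depth
    called : (m, n) bool, individual has data at locus
    popmap : optional population map
    """

    individuals: list[str]
    locus_ids: list[str]
    locus_lengths: np.ndarray
    snp_locus: np.ndarray
    snp_pos: np.ndarray
    geno: np.ndarray
    depth: np.ndarray
    called: np.ndarray
    popmap: PopulationMap | None = None

    def __post_init__(self) -> None:
        self.locus_lengths = np.asarray(self.locus_lengths, dtype=np.int64)
        self.snp_locus = np.asarray(self.snp_locus, dtype=np.int64)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.called = np.asarray(self.called, dtype=bool)
        if self.geno.shape != (len(self.snp_locus), len(self.individuals), 2):
            raise FormatError("genotype array shape mismatch")
        if self.depth.shape != (len(self.locus_ids), len(self.individuals)):
            raise FormatError("depth array shape mismatch")
        if np.any(self.snp_pos >= self.locus_lengths[self.snp_locus]):
            raise FormatError("SNP position beyond locus length")
        if np.any(self.depth < 0):
            raise FormatError("negative read depth")
        # an uncalled (locus, individual) must have missing genotypes
        uncalled = ~self.called[self.snp_locus]
        self.geno[uncalled] = _MISSING

    # ---------------------------------------------------------------- sizes
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_locus)

    # ------------------------------------------------------------- helpers
    def snp_called(self) -> np.ndarray:
        """(s, n) bool: genotype called at each SNP record."""
        return self.geno[:, :, 0] >= 0

    def snp_het(self) -> np.ndarray:
        """(s, n) bool: genotype called and heterozygous."""
        return self.snp_called() & (self.geno[:, :, 0] != self.geno[:, :, 1])

    def alleles_per_snp(self) -> np.ndarray:
        """(s,) number of distinct called alleles at each SNP."""
        counts = np.zeros(self.n_snps, dtype=np.int64)
        flat = self.geno.reshape(self.n_snps, -1)
        for a in range(4):
            counts += np.any(flat == a, axis=1)
        return counts

    def segregating_snp(self) -> np.ndarray:
        """(s,) bool: SNP still has >=2 alleles among called genotypes."""
        return self.alleles_per_snp() >= 2

    def presence_counts(self) -> np.ndarray:
        """(m,) number of individuals with data at each locus."""
        return self.called.sum(axis=1)

    def subset_loci(self, indices: np.ndarray) -> "LocusCatalog":
        """New catalog restricted to the given locus indices (order kept)."""
        indices = np.asarray(indices, dtype=np.int64)
        keep_snp = np.isin(self.snp_locus, indices)
        remap = {int(old): new for new, old in enumerate(indices)}
        new_snp_locus = np.array(
            [remap[int(l)] for l in self.snp_locus[keep_snp]], dtype=np.int64
        )
        order = np.argsort(new_snp_locus, kind="stable")
        return LocusCatalog(
            individuals=self.individuals,
            locus_ids=[self.locus_ids[i] for i in indices],
            locus_lengths=self.locus_lengths[indices],
            snp_locus=new_snp_locus[order],
            snp_pos=self.snp_pos[keep_snp][order],
            geno=self.geno[keep_snp][order].copy(),
            depth=self.depth[indices].copy(),
            called=self.called[indices].copy(),
            popmap=self.popmap,
        )

    def haplotype_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(2n, s) haplotype code matrix and per-row individual labels.

        Each individual contributes its two allele rows (phase as stored);
        missing genotypes are -1 in both rows.
        """
        n = self.n_individuals
        mat = np.empty((2 * n, self.n_snps), dtype=np.int8)
        mat[0::2] = self.geno[:, :, 0].T
        mat[1::2] = self.geno[:, :, 1].T
        labels = [ind for ind in self.individuals for _ in range(2)]
        return mat, labels

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LocusCatalog)
            and self.individuals == other.individuals
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.locus_lengths, other.locus_lengths)
            and np.array_equal(self.snp_locus, other.snp_locus)
            and np.array_equal(self.snp_pos, other.snp_pos)
            and np.array_equal(self.geno, other.geno)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.called, other.called)
        )

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path: str | Path) -> None:
        """Write the catalog TSV dialect.

        One row per (locus, individual): locus_id, position, individual,
        allele1, allele2, depth, locus_length.  Loci with several SNPs emit
        one row per SNP; loci with none emit a single row with position '.'
        and alleles '.'.  Uncalled genotypes carry '.' alleles.
        """
        with open(path, "w") as fh:
            fh.write("locus_id\tposition\tindividual\tallele1\tallele2\tdepth\tlocus_length\n")
            for li, lid in enumerate(self.locus_ids):
                snps = np.where(self.snp_locus == li)[0]
                for ii, ind in enumerate(self.individuals):
                    depth = self.depth[li, ii]
                    if len(snps) == 0:
                        # placeholder row: '-' = called but monomorphic,
                        # '.' = no data for this individual
                        a1 = a2 = "-" if self.called[li, ii] else "."
                        pos = "."
                        fh.write(
                            f"{lid}\t{pos}\t{ind}\t{a1}\t{a2}\t{depth}\t{self.locus_lengths[li]}\n"
                        )
                        continue
                    for si in snps:
                        g = self.geno[si, ii]
                        a1 = BASES[g[0]] if g[0] >= 0 else "."
                        a2 = BASES[g[1]] if g[1] >= 0 else "."
                        fh.write(
                            f"{lid}\t{self.snp_pos[si]}\t{ind}\t{a1}\t{a2}\t{depth}\t{self.locus_lengths[li]}\n"
                        )

    @classmethod
    def from_tsv(cls, path: str | Path, popmap: PopulationMap | None = None) -> "LocusCatalog":
        text = Path(path).read_text()
        lines = [l for l in text.splitlines() if l.strip()]
        if len(lines) <= 1:
            raise EmptyInputError(f"no catalog rows in {path}")
        header = lines[0].split("\t")
        if header[:6] != ["locus_id", "position", "individual", "allele1", "allele2", "depth"]:
            raise FormatError(f"unrecognized catalog header in {path}")

        individuals: list[str] = []
        locus_ids: list[str] = []
        lengths: dict[str, int] = {}
        rows: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
        depths: dict[tuple[str, str], int] = {}
        placeholder_called: dict[tuple[str, str], bool] = {}
        loci_seen: dict[str, None] = {}
        for line in lines[1:]:
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"bad catalog row: {line!r}")
            lid, pos, ind, a1, a2, depth, length = parts
            if ind not in individuals:
                individuals.append(ind)
            loci_seen.setdefault(lid, None)
            lengths[lid] = int(length)
            depths[(lid, ind)] = int(depth)
            if pos == ".":
                placeholder_called[(lid, ind)] = a1 == "-"
            else:
                key = (lid, int(pos))
                g1 = _CODE.get(a1, _MISSING)
                g2 = _CODE.get(a2, _MISSING)
                rows.setdefault(key, {})[ind] = (g1, g2)
        locus_ids = list(loci_seen)

        n = len(individuals)
        m = len(locus_ids)
        lidx = {lid: i for i, lid in enumerate(locus_ids)}
        iidx = {ind: i for i, ind in enumerate(individuals)}
        snp_keys = sorted(rows, key=lambda k: (lidx[k[0]], k[1]))
        s = len(snp_keys)
        geno = np.full((s, n, 2), _MISSING, dtype=np.int8)
        snp_locus = np.array([lidx[k[0]] for k in snp_keys], dtype=np.int64)
        snp_pos = np.array([k[1] for k in snp_keys], dtype=np.int64)
        for si, key in enumerate(snp_keys):
            for ind, (g1, g2) in rows[key].items():
                geno[si, iidx[ind]] = (g1, g2)
        depth = np.zeros((m, n), dtype=np.int64)
        for (lid, ind), d in depths.items():
            depth[lidx[lid], iidx[ind]] = d
        locus_lengths = np.array([lengths[lid] for lid in locus_ids], dtype=np.int64)

        called = np.ones((m, n), dtype=bool)
        # a (locus, individual) is uncalled when its SNP genotypes are missing
        for li in range(m):
            snps = np.where(snp_locus == li)[0]
            if len(snps):
                called[li] = geno[snps[0], :, 0] >= 0
            else:
                lid = locus_ids[li]
                for ind, ii in iidx.items():
                    called[li, ii] = placeholder_called.get((lid, ind), False)
        return cls(
            individuals, locus_ids, locus_lengths, snp_locus, snp_pos, geno, depth, called, popmap
        )


def mask_low_depth(catalog: LocusCatalog, min_depth: int) -> LocusCatalog:
    """Mask every genotype whose stack depth is below `min_depth`."""
    called = catalog.called & (catalog.depth >= min_depth)
    geno = catalog.geno.copy()
    geno[~called[catalog.snp_locus]] = _MISSING
    return replace(catalog, geno=geno, called=called)


def filter_catalog(
    catalog: LocusCatalog,
    min_depth: int = 5,
    max_snps: int = 2,
    min_individuals: int = 9,
    biallelic_only: bool = True,
) -> LocusCatalog:
    """Apply the catalog hygiene rules in order.

    1. depth mask: genotypes with depth < `min_depth` become missing;
    2. allele/SNP checks: drop loci with any >2-allele SNP (when
       `biallelic_only`) or more than `max_snps` SNPs still segregating
       after the depth mask;
    3. presence: drop loci called in fewer than `min_individuals`
       individuals.
    """
    if min_individuals > catalog.n_individuals:
        raise ConfigurationError(
            f"min_individuals={min_individuals} exceeds panel size {catalog.n_individuals}"
        )
    masked = mask_low_depth(catalog, min_depth)

    seg = masked.segregating_snp()
    alleles = masked.alleles_per_snp()
    keep = np.ones(masked.n_loci, dtype=bool)
    if biallelic_only:
        bad = np.unique(masked.snp_locus[alleles > 2])
        keep[bad] = False
    snp_counts = np.bincount(masked.snp_locus[seg], minlength=masked.n_loci)
    keep &= snp_counts <= max_snps
    keep &= masked.presence_counts() >= min_individuals
    return masked.subset_loci(np.where(keep)[0])


def export_genotype_matrix(
    catalog: LocusCatalog, path: str | Path, format: str = "tsv"
) -> None:
    """Write genotypes to `path` in a given dialect.

    "tsv" is the lossless catalog dialect (same as `LocusCatalog.to_tsv`);
    "genepop" is a Genepop-like matrix with 2-digit allele codes
    (A=01 .. T=04) and 0000 for missing, one POP block per region.
    """
    if format == "tsv":
        catalog.to_tsv(path)
        return
    if format != "genepop":
        raise FormatError(f"unknown export format {format!r}")

    popmap = catalog.popmap
    buf = _io.StringIO()
    buf.write("radscape genepop-like export\n")
    names = [
        f"{catalog.locus_ids[catalog.snp_locus[si]]}_{catalog.snp_pos[si]}"
        for si in range(catalog.n_snps)
    ]
    buf.write("\n".join(names) + "\n")

    if popmap is not None:
        groups = [(r, popmap.members(r)) for r in popmap.region_labels]
    else:
        groups = [("all", list(catalog.individuals))]
    for _, members in groups:
        buf.write("POP\n")
        for ind in members:
            ii = catalog.individuals.index(ind)
            codes = []
            for si in range(catalog.n_snps):
                g = catalog.geno[si, ii]
                if g[0] < 0:
                    codes.append("0000")
                else:
                    codes.append(f"{g[0] + 1:02d}{g[1] + 1:02d}")
            buf.write(f"{ind} ,  " + " ".join(codes) + "\n")
    Path(path).write_text(buf.getvalue())
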