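"""Alignment, population-map and haplotype-table I/O.

Sequences are held as int8 code matrices: A=0, C=1, G=2, T=3, and -1 for
anything uncalled (N or an alignment gap).  All comparisons downstream use
pairwise deletion over the called sites.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, FormatError

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

#: transition partners (A<->G, C<->T); everything else is a transversion
TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (-1 for N/gap/other)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c >= 0 else "N" for c in codes)


@dataclass
class PopulationMap:
    """individual -> (site, region) assignment.

    Region order is the sorted set of region labels; every grouped statistic
    in the package iterates regions in that order.
    """

    individuals: list[str]
    sites: dict[str, str]
    regions: dict[str, str]

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if ind not in self.regions:
                raise FormatError(f"individual {ind!r} missing from popmap")

    @property
    def region_labels(self) -> list[str]:
        return sorted(set(self.regions.values()))

    def region_of(self, individual: str) -> str:
        return self.regions[individual]

    def members(self, region: str) -> list[str]:
        return [i for i in self.individuals if self.regions[i] == region]

    @classmethod
    def read(cls, path: str | Path) -> "PopulationMap":
        individuals, sites, regions = [], {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"popmap line needs 3 tab-separated fields: {line!r}")
            ind, site, region = parts
            individuals.append(ind)
            sites[ind] = site
            regions[ind] = region
        if not individuals:
            raise EmptyInputError(f"empty popmap: {path}")
        return cls(individuals, sites, regions)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ind in self.individuals:
                fh.write(f"{ind}\t{self.sites[ind]}\t{self.regions[ind]}\n")


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid sequences with individual labels.

    `codes` has shape (n_sequences, length); rows follow `labels`.
    """

    labels: list[str]
    codes: np.ndarray
    popmap: PopulationMap | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise FormatError("alignment codes must be a 2-D matrix")
        if len(self.labels) != self.codes.shape[0]:
            raise FormatError("label/sequence count mismatch")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, label: str) -> str:
        return codes_to_seq(self.codes[self.labels.index(label)])

    def subset(self, labels: list[str]) -> "HaplotypeAlignment":
        idx = [self.labels.index(l) for l in labels]
        return HaplotypeAlignment(list(labels), self.codes[idx], self.popmap)

    def region_codes(self, region: str) -> np.ndarray:
        if self.popmap is None:
            raise FormatError("alignment has no population map attached")
        mask = [self.popmap.region_of(l) == region for l in self.labels]
        return self.codes[np.asarray(mask, dtype=bool)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HaplotypeAlignment)
            and self.labels == other.labels
            and np.array_equal(self.codes, other.codes)
        )


def read_fasta(path: str | Path, popmap: PopulationMap | None = None) -> HaplotypeAlignment:
    """Read an aligned FASTA file; sequences are upper-cased on input.

    Raises EmptyInputError on an empty file and FormatError on ragged input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    labels = [r.id for r in records]
    codes = np.vstack([seq_to_codes(str(r.seq)) for r in records])
    return HaplotypeAlignment(labels, codes, popmap)


def write_fasta(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(codes_to_seq(alignment.codes[i])), id=alignment.labels[i], description="")
        for i in range(alignment.n)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-region counts.

    `haplotypes` are the representative code arrays (rows), `region_counts`
    maps region -> array of counts aligned with the haplotype rows, and
    `assignment` maps each input label to its haplotype index.
    """

    haplotypes: np.ndarray
    region_counts: dict[str, np.ndarray]
    assignment: dict[str, int]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.length = self.haplotypes.shape[1] if self.haplotypes.size else 0

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def counts(self, region: str | None = None) -> np.ndarray:
        if region is not None:
            return self.region_counts[region]
        return np.sum([c for c in self.region_counts.values()], axis=0)

    @property
    def total(self) -> int:
        return int(self.counts().sum())


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two code rows agree at every site where both are called."""
    both = (a >= 0) & (b >= 0)
    return bool(np.all(a[both] == b[both]))


def collapse_haplotypes(alignment: HaplotypeAlignment) -> HaplotypeTable:
    """Merge identical sequences into haplotypes.

    N (uncalled) matches any base: a partially called sequence is merged into
    a fully called haplotype it is compatible with, choosing the
    lexicographically smallest compatible representative.  Partially called
    sequences compatible with no fully called haplotype stay distinct.
    """
    if alignment.n == 0:
        raise EmptyInputError("cannot collapse an empty alignment")
    full_mask = np.all(alignment.codes >= 0, axis=1)

    reps: list[np.ndarray] = []
    rep_keys: dict[bytes, int] = {}
    assignment: dict[str, int] = {}

    order = sorted(np.where(full_mask)[0], key=lambda i: codes_to_seq(alignment.codes[i]))
    for i in order:
        key = alignment.codes[i].tobytes()
        if key not in rep_keys:
            rep_keys[key] = len(reps)
            reps.append(alignment.codes[i])
    for i in np.where(full_mask)[0]:
        assignment[alignment.labels[i]] = rep_keys[alignment.codes[i].tobytes()]

    # partially called sequences: merge into the smallest compatible full rep
    for i in np.where(~full_mask)[0]:
        row = alignment.codes[i]
        hit = None
        for j, rep in enumerate(reps):
            if np.all(rep >= 0) and _compatible(row, rep):
                hit = j
                break  # reps with full calls are in lexicographic order
        if hit is None:
            for j, rep in enumerate(reps):
                if np.array_equal(rep, row):
                    hit = j
                    break
        if hit is None:
            hit = len(reps)
            reps.append(row)
        assignment[alignment.labels[i]] = hit

    regions: list[str]
    if alignment.popmap is not None:
        regions = alignment.popmap.region_labels
        region_of = {l: alignment.popmap.region_of(l) for l in alignment.labels}
    else:
        regions = ["all"]
        region_of = {l: "all" for l in alignment.labels}

    counts = {r: np.zeros(len(reps), dtype=int) for r in regions}
    for label, h in assignment.items():
        counts[region_of[label]][h] += 1

    return HaplotypeTable(np.vstack(reps), counts, assignment)
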