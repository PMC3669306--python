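"""Core data model shared by every stage of the quartet pipeline.

Allele coding is integer throughout: ``REF = 0``, ``ALT = 1``; ``MISSING``
marks an uncalled allele and ``DEL`` a hemizygous (deleted) homolog, which
only appears after hemizygous correction.

Coordinate contract: VCF positions are 1-based (``QuartetSite.pos``); every
interval in a :class:`RegionSet` (and in BED files) is 0-based, half-open.
Conversions happen in :mod:`quartet_phase.vcf_io` and nowhere else.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator

REF = 0
ALT = 1
MISSING = -1
DEL = 2

#: Pedigree roles, in the order used everywhere (including VCF columns).
ROLES = ("father", "mother", "child1", "child2")
PARENTS = ("father", "mother")
CHILDREN = ("child1", "child2")

#: phase_source tiers, in precedence order (earlier never overridden by later).
PHASE_TIERS = ("transmission", "physical", "population", "unphased")

#: inheritance-state labels: did the two children inherit the same parental
#: homolog (+1 markers) or different ones (-1 markers)?
SAME = "same"
DIFFERENT = "different"

ALLELE_SYMBOL = {REF: "0", ALT: "1", MISSING: ".", DEL: "-"}


@dataclass(frozen=True, slots=True)
class Pedigree:
    """Names of the four samples: two parents and two full siblings."""

    father_id: str
    mother_id: str
    child1_id: str
    child2_id: str

    def __post_init__(self) -> None:
        names = [self.father_id, self.mother_id, self.child1_id, self.child2_id]
        if len(set(names)) != 4:
            raise ValueError(f"pedigree sample names must be distinct: {names}")

    @property
    def sample_ids(self) -> tuple[str, str, str, str]:
        return (self.father_id, self.mother_id, self.child1_id, self.child2_id)

    def role_of(self, sample_id: str) -> str:
        for role, name in zip(ROLES, self.sample_ids):
            if name == sample_id:
                return role
        raise KeyError(sample_id)

    def sample_of(self, role: str) -> str:
        return dict(zip(ROLES, self.sample_ids))[role]


@dataclass(slots=True)
class Genotype:
    """A diploid genotype: an unordered allele pair, optionally phased.

    When ``phased`` is true, ``(a, b)`` is the ordered pair; the ordering
    convention is Maternal|Paternal for children and
    Transmitted-to-child1|Other for parents.
    """

    a: int
    b: int
    phased: bool = False

    @classmethod
    def unphased(cls, a: int, b: int) -> "Genotype":
        lo, hi = sorted((a, b))
        return cls(lo, hi, False)

    @classmethod
    def phased_pair(cls, first: int, second: int) -> "Genotype":
        return cls(first, second, True)

    @property
    def alleles(self) -> tuple[int, int]:
        """Unordered (canonically sorted) allele pair."""
        return tuple(sorted((self.a, self.b)))  # type: ignore[return-value]

    @property
    def ordered(self) -> tuple[int, int] | None:
        return (self.a, self.b) if self.phased else None

    def is_missing(self) -> bool:
        return self.a == MISSING or self.b == MISSING

    def is_het(self) -> bool:
        return not self.is_missing() and self.a != self.b

    def is_hom(self) -> bool:
        return not self.is_missing() and self.a == self.b

    def carries(self, allele: int) -> bool:
        return allele in (self.a, self.b)

    def with_order(self, first: int, second: int) -> "Genotype":
        if tuple(sorted((first, second))) != self.alleles:
            raise ValueError("phasing must not alter the unordered genotype")
        return Genotype(first, second, True)

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return f"{ALLELE_SYMBOL[self.a]}{sep}{ALLELE_SYMBOL[self.b]}"


@dataclass(slots=True)
class QuartetSite:
    """One biallelic variant position with the four genotypes."""

    chrom: str
    pos: int  # 1-based, per VCF
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    pl: dict[str, tuple[int, int, int] | None] = field(default_factory=dict)
    filter_status: tuple[str, ...] = ("PASS",)
    phase_source: dict[str, str] = field(default_factory=dict)
    parental_origin: dict[str, str] = field(default_factory=dict)
    error_class: str | None = None  # "MIE" | "SCE" | None
    hemizygous: tuple[str, ...] = ()
    notes: list[str] = field(default_factory=list)

    def gt(self, role: str) -> Genotype:
        return self.genotypes[role]

    def fully_called(self) -> bool:
        return not any(self.genotypes[r].is_missing() for r in ROLES)

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def source(self, role: str) -> str:
        return self.phase_source.get(role, "unphased")

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class RegionSet:
    """Per-chromosome sorted, non-overlapping 0-based half-open intervals."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None,
                 label: str = ""):
        self.label = label
        self._ivs: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                for start, end in ivs:
                    self.add(chrom, start, end)
            self.normalize()

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"empty or inverted interval [{start}, {end})")
        self._ivs.setdefault(chrom, []).append((start, end))

    def normalize(self) -> "RegionSet":
        """Sort and merge overlapping or adjacent intervals, in place."""
        for chrom, ivs in self._ivs.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._ivs[chrom] = merged
        return self

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._ivs.get(chrom, []))

    def chroms(self) -> list[str]:
        return sorted(self._ivs)

    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._ivs.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms():
            for s, e in self._ivs[chrom]:
                yield chrom, s, e

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self._ivs == other._ivs


def sites_sorted(sites: Iterable[QuartetSite]) -> bool:
    """True if positions strictly increase within each chromosome."""
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            return False
        last[s.chrom] = s.pos
    return True
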