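"""Structural-variant consensus merging and hemizygous error correction.

SV calls from several callers are believed only when at least two callers
report an overlapping variant of the same type; the consensus coordinates
come from the designated primary caller when it contributed, otherwise from
the largest remaining call. Heterozygous deletions make the variant caller
report hemizygous SNPs as homozygous, which manifests as Mendelian
inheritance errors; once the deletions are genotyped, those MIEs can be
re-evaluated with an explicit DEL allele and corrected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .blocks import BlockMap
from .mendel import mendel_consistent, state_assignment_exists
from .model import DEL, ROLES, Genotype, QuartetSite

MIN_SV_LENGTH = 100  # consensus candidates must exceed 100 bp


@dataclass(slots=True)
class SVCall:
    chrom: str
    start: int                    # 0-based half-open
    end: int
    svtype: str                   # "DEL" | "DUP"
    caller: str
    genotypes: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SVCall") -> bool:
        return (self.chrom == other.chrom and self.svtype == other.svtype
                and self.start < other.end and other.start < self.end)


def merge_sv_calls(calls: list[SVCall], primary_caller: str = "pindel"
                   ) -> list[SVCall]:
    """Keep overlapping same-type calls reported by >= 2 distinct callers.

    Overlap of a single base pair suffices, regardless of reciprocal
    fraction. Clusters are connected components of the overlap relation; the
    representative is the primary caller's call when present (leftmost if
    several), otherwise the largest call. Calls not exceeding the minimum SV
    length are dropped beforehand; merging is symmetric in input order.
    """
    cands = sorted((c for c in calls if c.length > MIN_SV_LENGTH),
                   key=lambda c: (c.chrom, c.start, c.end, c.caller))
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if cands[j].chrom != cands[i].chrom or cands[j].start >= cands[i].end:
                break  # sorted by (chrom, start): nothing further overlaps i
            if cands[i].overlaps(cands[j]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[SVCall]] = {}
    for i, c in enumerate(cands):
        clusters.setdefault(find(i), []).append(c)
    consensus = []
    for members in clusters.values():
        if len({m.caller for m in members}) < 2:
            continue
        primaries = [m for m in members if m.caller == primary_caller]
        if primaries:
            rep = min(primaries, key=lambda m: (m.start, m.end))
        else:
            rep = max(members, key=lambda m: (m.length, -m.start))
        consensus.append(rep)
    consensus.sort(key=lambda c: (c.chrom, c.start, c.end))
    return consensus


def _effective_alleles(site: QuartetSite, deletion: SVCall
                       ) -> dict[str, tuple[int, int]] | None:
    """Allele pairs with DEL substituted on deleted homologs, or None.

    A member heterozygous for the deletion has one homolog missing at the
    site, so its (necessarily homozygous-looking) call covers only the
    remaining homolog. Unknown deletion genotypes make the site
    uncorrectable.
    """
    eff: dict[str, tuple[int, int]] = {}
    hemi = False
    for role in ROLES:
        dgt = deletion.genotypes.get(role)
        if dgt is None:
            return None
        sgt = site.gt(role).alleles
        if dgt == (0, 1):
            if sgt[0] != sgt[1]:
                return None  # het call under a het deletion: inconsistent
            eff[role] = (sgt[0], DEL)
            hemi = True
        elif dgt == (1, 1):
            return None  # homozygous deletion: no callable genotype here
        else:
            eff[role] = sgt
    return eff if hemi else None


def hemizygous_correct(sites: list[QuartetSite], deletions: list[SVCall],
                       blocks: BlockMap | None = None) -> int:
    """Clear MIEs explained by hemizygosity over heterozygous deletions.

    For each MIE site inside a consensus deletion that is heterozygous in at
    least one member, Mendel consistency is re-evaluated treating the
    deleted homolog's allele as DEL (which transmits like any allele, so a
    child's DEL must come from a deletion-carrying parent). If block states
    are available the re-evaluation also requires consistency with the
    inheritance pattern. Corrected sites have their error class cleared and
    the affected genotypes marked hemizygous. Returns the number of MIEs
    resolved; never touches non-MIE sites.
    """
    dels = [d for d in deletions if d.svtype == "DEL"]
    n_resolved = 0
    for site in sites:
        if site.error_class != "MIE":
            continue
        pos0 = site.pos - 1
        for deletion in dels:
            if deletion.chrom != site.chrom or not (deletion.start <= pos0 < deletion.end):
                continue
            eff = _effective_alleles(site, deletion)
            if eff is None:
                continue
            args = (eff["mother"], eff["father"], eff["child1"], eff["child2"])
            s_m = blocks.state_at("mother", site.chrom, site.pos) if blocks else None
            s_p = blocks.state_at("father", site.chrom, site.pos) if blocks else None
            if s_m is not None and s_p is not None:
                ok = state_assignment_exists(*args, s_m, s_p)
            else:
                ok = mendel_consistent(*args)
            if ok:
                site.error_class = None
                hemi_roles = tuple(r for r in ROLES if DEL in eff[r])
                site.hemizygous = hemi_roles
                for role in hemi_roles:
                    site.genotypes[role] = Genotype.unphased(eff[role][0], DEL)
                n_resolved += 1
                break
    return n_resolved
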