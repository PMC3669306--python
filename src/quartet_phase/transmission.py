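"""Phasing by Mendelian transmission within the two parent-child trios.

The quartet is split into two father-mother-child trios. Within a trio a
site is phasable whenever at least one member is homozygous: homozygous
genotypes are trivially phased seeds, and the heterozygous members are then
forced by Mendel's laws. Children are ordered Maternal|Paternal; parents are
anchored Transmitted-to-child1|Other so the quartet output is deterministic.
Sites heterozygous in all three trio members (triple-het) need the
inheritance blocks; sites heterozygous in all four members (quadruple-het)
cannot be phased by transmission at all.
"""
from __future__ import annotations

from dataclasses import dataclass

from .blocks import BlockMap
from .mendel import trio_assignments
from .model import CHILDREN, SAME, Genotype, QuartetSite

PHASED = "phased"
TRIPLE_HET = "triple_het"
MIE_STATUS = "mie"
MISSING_STATUS = "missing"


@dataclass(slots=True)
class TrioPhaseResult:
    status: str
    child_ordered: tuple[int, int] | None = None   # (maternal, paternal)
    mother_ordered: tuple[int, int] | None = None  # (transmitted, other)
    father_ordered: tuple[int, int] | None = None


def _other_allele(alleles: tuple[int, int], transmitted: int) -> int:
    a, b = alleles
    return b if a == transmitted else a


def phase_site_in_trio(mother: Genotype, father: Genotype,
                       child: Genotype) -> TrioPhaseResult:
    """Phase one site within one trio, if Mendel forces a unique assignment."""
    if mother.is_missing() or father.is_missing() or child.is_missing():
        return TrioPhaseResult(MISSING_STATUS)
    asg = trio_assignments(mother.alleles, father.alleles, child.alleles)
    if not asg:
        return TrioPhaseResult(MIE_STATUS)
    if len(asg) > 1:
        # possible only when mother, father and child are all heterozygous
        return TrioPhaseResult(TRIPLE_HET)
    mt, ft = next(iter(asg))
    return TrioPhaseResult(
        PHASED,
        child_ordered=(mt, ft),
        mother_ordered=(mt, _other_allele(mother.alleles, mt)),
        father_ordered=(ft, _other_allele(father.alleles, ft)),
    )


@dataclass(slots=True)
class QuartetPhaseSummary:
    n_sites: int = 0
    n_phased_both: int = 0       # both children phased
    n_quad_het: int = 0
    n_triple_het: int = 0        # exactly one trio left ambiguous
    n_mie: int = 0
    n_missing: int = 0


def phase_quartet(sites: list[QuartetSite]) -> QuartetPhaseSummary:
    """Phase every site independently in both trios and reconcile.

    Mutates genotypes in place (setting ordered pairs and
    ``phase_source="transmission"``) and returns a tally. Mendel-inconsistent
    sites are left untouched for error analysis; sites with any missing
    genotype are excluded from transmission phasing.
    """
    summary = QuartetPhaseSummary()
    for site in sites:
        summary.n_sites += 1
        if not site.fully_called():
            summary.n_missing += 1
            continue
        mother, father = site.gt("mother"), site.gt("father")
        res1 = phase_site_in_trio(mother, father, site.gt("child1"))
        res2 = phase_site_in_trio(mother, father, site.gt("child2"))
        if MIE_STATUS in (res1.status, res2.status):
            summary.n_mie += 1
            continue
        if res1.status == TRIPLE_HET and res2.status == TRIPLE_HET:
            summary.n_quad_het += 1
            continue
        for child, res in (("child1", res1), ("child2", res2)):
            if res.status == PHASED:
                site.genotypes[child] = site.gt(child).with_order(*res.child_ordered)
                site.phase_source[child] = "transmission"
        if res1.status == PHASED:
            # parent anchor: transmitted-to-child1 first
            site.genotypes["mother"] = mother.with_order(*res1.mother_ordered)
            site.genotypes["father"] = father.with_order(*res1.father_ordered)
            site.phase_source["mother"] = "transmission"
            site.phase_source["father"] = "transmission"
        if res1.status == PHASED and res2.status == PHASED:
            summary.n_phased_both += 1
        else:
            summary.n_triple_het += 1
    return summary


def resolve_triple_het(sites: list[QuartetSite], blocks: BlockMap) -> int:
    """Phase triple-heterozygous sites using the inheritance blocks.

    Where one trio is all-heterozygous but the other trio resolves the
    transmitted parental alleles, the block states propagate the phase to
    the unresolved child (and anchor the parents to child1). Sites inside a
    crossover junction are left unresolved; a propagation that contradicts
    the observed genotype marks the site as an SCE candidate instead of
    phasing it. Returns the number of newly phased sites.
    """
    n_resolved = 0
    for site in sites:
        if not site.fully_called():
            continue
        mother, father = site.gt("mother"), site.gt("father")
        res = {c: phase_site_in_trio(mother, father, site.gt(c)) for c in CHILDREN}
        statuses = {c: r.status for c, r in res.items()}
        if sorted(statuses.values()) != [PHASED, TRIPLE_HET]:
            continue
        known = "child1" if statuses["child1"] == PHASED else "child2"
        unknown = "child2" if known == "child1" else "child1"
        s_m = blocks.state_at("mother", site.chrom, site.pos)
        s_p = blocks.state_at("father", site.chrom, site.pos)
        if s_m is None or s_p is None:
            continue  # junction or uncovered: leave unresolved
        mt_known, ft_known = res[known].child_ordered
        mt = mt_known if s_m == SAME else _other_allele(mother.alleles, mt_known)
        ft = ft_known if s_p == SAME else _other_allele(father.alleles, ft_known)
        if tuple(sorted((mt, ft))) != site.gt(unknown).alleles:
            if "sce_candidate" not in site.notes:
                site.notes.append("sce_candidate")
            continue
        site.genotypes[unknown] = site.gt(unknown).with_order(mt, ft)
        site.phase_source[unknown] = "transmission"
        # anchor parents to child1
        mt1, ft1 = (mt, ft) if unknown == "child1" else res["child1"].child_ordered
        site.genotypes["mother"] = mother.with_order(
            mt1, _other_allele(mother.alleles, mt1))
        site.genotypes["father"] = father.with_order(
            ft1, _other_allele(father.alleles, ft1))
        site.phase_source["mother"] = "transmission"
        site.phase_source["father"] = "transmission"
        n_resolved += 1
    return n_resolved
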