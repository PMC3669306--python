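"""Mendelian transmission primitives on unordered allele pairs.

All functions operate on unordered genotypes given as 2-tuples of integer
allele codes and enumerate the possible gamete assignments explicitly: an
assignment is a choice ``(m1, f1, m2, f2)`` of one maternal and one paternal
allele for each child. These enumerations are tiny (at most 16 assignments)
and serve as the single source of truth for Mendel consistency, transmission
determination and state (inheritance-pattern) consistency. Allele codes are
opaque: the DEL code used by hemizygous correction transmits like any other
allele.
"""
from __future__ import annotations

from itertools import product

from .model import DIFFERENT, SAME

Alleles = tuple[int, int]


def assignments(mother: Alleles, father: Alleles, child1: Alleles,
                child2: Alleles) -> list[tuple[int, int, int, int]]:
    """All gamete assignments reproducing both children's genotypes."""
    out = []
    for m1, f1, m2, f2 in product(mother, father, mother, father):
        if (tuple(sorted((m1, f1))) == tuple(sorted(child1))
                and tuple(sorted((m2, f2))) == tuple(sorted(child2))):
            out.append((m1, f1, m2, f2))
    return out


def mendel_consistent(mother: Alleles, father: Alleles, child1: Alleles,
                      child2: Alleles) -> bool:
    return bool(assignments(mother, father, child1, child2))


def trio_assignments(mother: Alleles, father: Alleles,
                     child: Alleles) -> set[tuple[int, int]]:
    """Distinct (maternal, paternal) allele assignments for one child."""
    want = tuple(sorted(child))
    return {(m, f) for m in mother for f in father
            if tuple(sorted((m, f))) == want}


def determined_transmissions(
        mother: Alleles, father: Alleles, child1: Alleles,
        child2: Alleles) -> dict[str, tuple[int, int] | None]:
    """Transmitted alleles per parent, where uniquely determined.

    Returns, for each of ``"mother"`` and ``"father"``, the pair of alleles
    transmitted to (child1, child2) if that pair is the same in every
    Mendel-consistent assignment, else None. An empty assignment set (a
    Mendelian inheritance error) yields None for both parents.
    """
    asg = assignments(mother, father, child1, child2)
    out: dict[str, tuple[int, int] | None] = {"mother": None, "father": None}
    if not asg:
        return out
    for parent, (i1, i2) in (("mother", (0, 2)), ("father", (1, 3))):
        t1 = {a[i1] for a in asg}
        t2 = {a[i2] for a in asg}
        if len(t1) == 1 and len(t2) == 1:
            out[parent] = (t1.pop(), t2.pop())
    return out


def state_assignment_exists(mother: Alleles, father: Alleles, child1: Alleles,
                            child2: Alleles, maternal_state: str,
                            paternal_state: str) -> bool:
    """Is there a phase assignment compatible with the inheritance states?

    The states say whether the two children inherited the same parental
    homolog: under ``SAME`` a parent transmits the same homolog (hence the
    same allele) to both children, under ``DIFFERENT`` the two homologs.
    """
    for mo in (mother, mother[::-1]):
        for fo in (father, father[::-1]):
            if tuple(sorted((mo[0], fo[0]))) != tuple(sorted(child1)):
                continue
            m2 = mo[0] if maternal_state == SAME else mo[1]
            f2 = fo[0] if paternal_state == SAME else fo[1]
            if tuple(sorted((m2, f2))) == tuple(sorted(child2)):
                return True
    return False


def marker_values(mother: Alleles, father: Alleles, child1: Alleles,
                  child2: Alleles) -> dict[str, str | None]:
    """Observed inheritance-state markers per parent, where determinable.

    A parent contributes a marker only when it is heterozygous (so its two
    alleles identify its two homologs) and the alleles it transmitted to both
    children are uniquely determined. The marker value is ``SAME`` (the +1
    track) when both children received the same allele, ``DIFFERENT`` (-1)
    otherwise.
    """
    det = determined_transmissions(mother, father, child1, child2)
    out: dict[str, str | None] = {"mother": None, "father": None}
    for parent, gt in (("mother", mother), ("father", father)):
        t = det[parent]
        if gt[0] != gt[1] and t is not None:
            out[parent] = SAME if t[0] == t[1] else DIFFERENT
    return out
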