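"""Shared builders and independent oracles for the test suite.

Oracles here re-derive expected behavior from first principles (explicit
enumeration of gamete choices and phase assignments) without calling the
package's own Mendel machinery, so implementation and expectation stay
independent.
"""
from itertools import product

from quartet_phase.model import (ALT, DIFFERENT, REF, ROLES, SAME, Genotype,
                                 QuartetSite)

GT_COMBOS = [(REF, REF), (REF, ALT), (ALT, ALT)]
STATES = [(a, b) for a in (SAME, DIFFERENT) for b in (SAME, DIFFERENT)]


def make_site(father, mother, child1, child2, chrom="chr1", pos=100,
              pl=None, filters=("PASS",)):
    """QuartetSite from unordered allele pairs (father, mother, c1, c2)."""
    gts = {"father": Genotype.unphased(*father),
           "mother": Genotype.unphased(*mother),
           "child1": Genotype.unphased(*child1),
           "child2": Genotype.unphased(*child2)}
    pls = dict.fromkeys(ROLES) if pl is None else dict(pl)
    return QuartetSite(chrom=chrom, pos=pos, ref="A", alt="G",
                       genotypes=gts, pl=pls, filter_status=tuple(filters))


def oracle_trio_phasings(mother, father, child):
    """All (maternal, paternal) gamete picks reproducing the child."""
    out = set()
    for m in mother:
        for f in father:
            if sorted((m, f)) == sorted(child):
                out.add((m, f))
    return out


def oracle_quartet_mie(mother, father, child1, child2):
    """Brute force: no gamete assignment reproduces both children."""
    for m1, f1, m2, f2 in product(mother, father, mother, father):
        if (sorted((m1, f1)) == sorted(child1)
                and sorted((m2, f2)) == sorted(child2)):
            return False
    return True


def oracle_marker_sce(mother, father, child1, child2, s_m, s_p):
    """Brute-force SCE oracle: determined transmission vs block state.

    Collect every gamete assignment; for a heterozygous parent whose
    transmitted alleles to both children are the same across all
    assignments, the implied same/different marker must match the state.
    """
    asg = [(m1, f1, m2, f2)
           for m1, f1, m2, f2 in product(mother, father, mother, father)
           if sorted((m1, f1)) == sorted(child1)
           and sorted((m2, f2)) == sorted(child2)]
    if not asg:
        return None  # MIE, not SCE
    for het, state, (i, j) in ((mother, s_m, (0, 2)), (father, s_p, (1, 3))):
        if het[0] == het[1]:
            continue
        first = {a[i] for a in asg}
        second = {a[j] for a in asg}
        if len(first) == 1 and len(second) == 1:
            marker = SAME if first == second else DIFFERENT
            if marker != state:
                return True
    return False


def oracle_min_penalty_segmentation_cost(values, r):
    """Exhaustive minimal cost of (#mismatches + r x #switches), n <= ~16."""
    n = len(values)
    best = None
    for bits in range(2 ** n):
        states = [1 if (bits >> i) & 1 else -1 for i in range(n)]
        cost = sum(v != s for v, s in zip(values, states))
        cost += r * sum(a != b for a, b in zip(states, states[1:]))
        if best is None or cost < best:
            best = cost
    return best


def oracle_segment_cost_quadratic(values, r):
    """Independent O(n^2) segment DP for the same objective."""
    n = len(values)
    # prefix[i] = number of +1 among first i values
    prefix = [0]
    for v in values:
        prefix.append(prefix[-1] + (v == 1))

    def mismatches(i, j, state):  # segment [i, j) constant state
        plus = prefix[j] - prefix[i]
        return (j - i - plus) if state == 1 else plus

    INF = float("inf")
    best = {1: [INF] * (n + 1), -1: [INF] * (n + 1)}
    best[1][0] = best[-1][0] = 0.0
    for j in range(1, n + 1):
        for state in (1, -1):
            b = INF
            for i in range(j):
                base = best[-state][i] + (r if i else 0)
                if i == 0:
                    base = min(base, best[state][0])
                b = min(b, base + mismatches(i, j, state))
            best[state][j] = b
    return min(best[1][n], best[-1][n])


def oracle_nx(spans, x):
    """Cumulative-scan Nx oracle."""
    spans = sorted(spans, reverse=True)
    total = sum(spans)
    acc = 0
    for s in spans:
        acc += s
        if acc >= total * x / 100.0:
            return s
    raise AssertionError("unreachable")
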