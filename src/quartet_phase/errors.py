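"""Transmission error analysis: MIE/SCE classification and error-rate estimators.

Two kinds of genotype error are genetically detectable in a sequenced
quartet. A Mendelian inheritance error (MIE) is a combination of the four
genotypes that no assignment of parental gametes can produce. A state
consistency error (SCE) is Mendel-consistent but contradicts the chromosome
transmission map: the site's determined transmission marker (same/different
parental homolog to the two children) disagrees with the inheritance-block
state at that position. MIEs and SCEs together are the genetically
detectable errors (GDEs); assuming a fraction d of all errors is detectable
(default 0.75), the undetected errors number GDE x (1-d)/d, which feeds the
false-positive and true-variant estimators.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

from .blocks import BlockMap
from .mendel import marker_values, mendel_consistent
from .model import (ALT, CHILDREN, DIFFERENT, PARENTS, REF, ROLES, SAME,
                    QuartetSite, RegionSet)

MIE = "MIE"
SCE = "SCE"


def classify_mie(site: QuartetSite) -> bool | None:
    """True if no parental gamete assignment reproduces both children.

    Returns None when any genotype is missing (not classifiable).
    """
    if not site.fully_called():
        return None
    return not mendel_consistent(*(site.gt(r).alleles for r in ROLES))


def classify_sce(site: QuartetSite, blocks: BlockMap) -> bool | None:
    """True if the site's determined transmission contradicts the block state.

    The check is marker-based, exactly as detection happens on the +-1
    comparison tracks: a parent is checkable only when it is heterozygous and
    the alleles it transmitted to both children are uniquely determined from
    the genotypes. Sites inside a crossover junction (no block state) and
    sites whose transmission is ambiguous are not classifiable and return
    None; Mendel-inconsistent sites also return None (they are MIEs).
    """
    if not site.fully_called():
        return None
    gts = tuple(site.gt(r).alleles for r in ("mother", "father", "child1", "child2"))
    if not mendel_consistent(*gts):
        return None
    markers = marker_values(*gts)
    checkable = False
    for parent in ("mother", "father"):
        marker = markers[parent]
        if marker is None:
            continue
        state = blocks.state_at(parent, site.chrom, site.pos)
        if state is None:
            continue  # junction or uncovered: ambiguous
        checkable = True
        if marker != state:
            return True
    return False if checkable else None


def classify_sites(sites: list[QuartetSite], blocks: BlockMap) -> dict[str, int]:
    """Set ``error_class`` on every fully-called site; return counts."""
    counts = {"n_called": 0, "n_mie": 0, "n_sce": 0}
    for site in sites:
        if not site.fully_called():
            continue
        counts["n_called"] += 1
        if classify_mie(site):
            site.error_class = MIE
            counts["n_mie"] += 1
        elif classify_sce(site, blocks):
            site.error_class = SCE
            counts["n_sce"] += 1
        else:
            site.error_class = None
    return counts


# ---------------------------------------------------------------------------
# Error-rate and true-variant estimators
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ErrorReport:
    """GDE bookkeeping for one call set (one filter stage)."""

    n_called: int
    n_mie: int
    n_sce: int
    detectable_fraction: float = 0.75

    @property
    def n_gde(self) -> int:
        return self.n_mie + self.n_sce

    @property
    def gde_corrected(self) -> int:
        """Sites that are neither MIE nor SCE."""
        return self.n_called - self.n_gde

    @property
    def undetected(self) -> float:
        """Estimated errors that escaped detection: GDE x (1-d)/d."""
        d = self.detectable_fraction
        return self.n_gde * (1.0 - d) / d

    @property
    def fp_pct(self) -> float:
        """False-positive rate (%): undetected errors per GDE-corrected site."""
        if self.gde_corrected == 0:
            return float("nan")
        return 100.0 * self.undetected / self.gde_corrected

    @property
    def true_variant_estimate(self) -> int:
        """Called sites minus detected and (rounded) undetected errors."""
        return self.n_called - self.n_gde - round(self.undetected)

    def fn_pct(self, baseline: "ErrorReport | int") -> float:
        """False-negative rate (%) of this (filtered) set against a baseline.

        Defined as the GDE-corrected sites lost relative to those remaining:
        100 x (baseline_corrected - corrected) / corrected.
        """
        base = baseline.gde_corrected if isinstance(baseline, ErrorReport) else baseline
        if self.gde_corrected == 0:
            return float("nan")
        return 100.0 * (base - self.gde_corrected) / self.gde_corrected


def gde_report(sites: list[QuartetSite], blocks: BlockMap | None = None,
               detectable_fraction: float = 0.75,
               classified: bool = False) -> ErrorReport:
    """Build an :class:`ErrorReport` from sites, classifying them if needed."""
    if not classified:
        if blocks is None:
            raise ValueError("blocks required to classify sites")
        classify_sites(sites, blocks)
    n_called = n_mie = n_sce = 0
    for s in sites:
        if not s.fully_called():
            continue
        n_called += 1
        if s.error_class == MIE:
            n_mie += 1
        elif s.error_class == SCE:
            n_sce += 1
    return ErrorReport(n_called, n_mie, n_sce, detectable_fraction)


def estimate_true_variants(n_called: int, n_gde: int,
                           detectable_fraction: float = 0.75) -> int:
    """Lower bound on true variants given detected errors.

    n_called - n_gde - round(n_gde x (1-d)/d); with d = 0.75 the undetected
    term is one third of the detected errors.
    """
    if not 0.0 < detectable_fraction <= 1.0:
        raise ValueError("detectable_fraction must be in (0, 1]")
    undetected = n_gde * (1.0 - detectable_fraction) / detectable_fraction
    return n_called - n_gde - round(undetected)


def filter_false_negative_pct(baseline_corrected: int, corrected: int) -> float:
    """FN% of a filter stage: corrected sites lost per corrected site kept."""
    return 100.0 * (baseline_corrected - corrected) / corrected


# ---------------------------------------------------------------------------
# Detectability enumeration
# ---------------------------------------------------------------------------

_HAPS = ((REF, REF), (REF, ALT), (ALT, REF), (ALT, ALT))
_STATES = tuple(product((SAME, DIFFERENT), repeat=2))
_GENOTYPES = ((REF, REF), (REF, ALT), (ALT, ALT))

Config = tuple[tuple[int, int], tuple[int, int], str, str]


def quartet_configurations() -> list[Config]:
    """Phased parental genotypes x inheritance states yielding a variant site.

    Child 1 inherits the first-listed homolog of each parent; the state pair
    then fixes child 2. The configuration where every allele is REF is
    excluded (no variant would be called there).
    """
    out = []
    for mh, fh, (sm, sp) in product(_HAPS, _HAPS, _STATES):
        if mh == (REF, REF) and fh == (REF, REF):
            continue
        out.append((mh, fh, sm, sp))
    return out


def true_haplotypes(config: Config) -> dict[str, tuple[int, int]]:
    mh, fh, sm, sp = config
    c1 = (mh[0], fh[0])
    c2 = (mh[0] if sm == SAME else mh[1], fh[0] if sp == SAME else fh[1])
    return {"mother": mh, "father": fh, "child1": c1, "child2": c2}


def classify_corrupted(genotypes: dict[str, tuple[int, int]], maternal_state: str,
                       paternal_state: str) -> str | None:
    """Classify an observed quartet given the true inheritance state.

    Returns "MIE", "SCE" or None (undetected). Uses the same marker-based
    SCE rule as :func:`classify_sce`.
    """
    gts = tuple(tuple(sorted(genotypes[r]))
                for r in ("mother", "father", "child1", "child2"))
    if not mendel_consistent(*gts):
        return MIE
    markers = marker_values(*gts)
    for parent, state in (("mother", maternal_state), ("father", paternal_state)):
        if markers[parent] is not None and markers[parent] != state:
            return SCE
    return None


@dataclass(slots=True)
class DetectabilityTable:
    """Detection fractions from the exhaustive miscall enumeration."""

    detect_children: float
    detect_parents: float
    per_config: dict = field(default_factory=dict)

    @property
    def detect_overall(self) -> float:
        return 0.5 * (self.detect_children + self.detect_parents)


def _corruptions(true_gt: tuple[int, int], model: str):
    """Distinct erroneous unordered genotypes for one member."""
    tg = tuple(sorted(true_gt))
    if model == "genotype":
        for bad in _GENOTYPES:
            if bad != tg:
                yield bad
    elif model == "allele":
        for i in (0, 1):
            obs = list(true_gt)
            obs[i] = ALT if obs[i] == REF else REF
            yield tuple(sorted(obs))
    else:
        raise ValueError(f"unknown error model {model!r}")


def enumerate_detectability(multiplicity: str = "sporadic",
                            error_model: str = "genotype",
                            weights: dict[Config, float] | None = None
                            ) -> DetectabilityTable:
    """Exhaustive enumeration of error detectability by transmission analysis.

    For every parental phased-genotype x inheritance-state configuration the
    true quartet genotypes are derived, each possible miscall is applied, and
    the corrupted quartet is classified MIE / SCE / undetected given the true
    state. Detection fractions are averaged over configurations (uniformly,
    unless ``weights`` maps configurations to weights), separately for errors
    landing in the children and in the parents.

    Error models: ``"genotype"`` (default) enumerates every distinct wrong
    genotype of a single member, the unit in which miscalls are tallied;
    ``"allele"`` enumerates single-allele flips, matching an error process
    that hits one of the eight sequenced haplotypes (use this to predict the
    flagged fraction for a simulator that injects allele flips). Corruptions
    that erase the variant entirely (all members hom-REF: the site would
    never enter a call set) are excluded from the denominators.

    ``multiplicity="non_sporadic"`` instead applies every pair of
    single-allele flips hitting two different members; pairs within the
    children (resp. parents) populate the two fractions.
    """
    if multiplicity not in ("sporadic", "non_sporadic"):
        raise ValueError(f"unknown multiplicity {multiplicity!r}")
    num = {"child": 0.0, "parent": 0.0}
    den = {"child": 0.0, "parent": 0.0}
    per_config: dict = {}
    for config in quartet_configurations():
        w = 1.0 if weights is None else weights.get(config, 0.0)
        if w == 0.0:
            continue
        truth = true_haplotypes(config)
        sm, sp = config[2], config[3]
        local = {"child": [0, 0], "parent": [0, 0]}  # detected, total
        if multiplicity == "sporadic":
            for role in ROLES:
                side = "child" if role in CHILDREN else "parent"
                for bad in _corruptions(truth[role], error_model):
                    obs = {r: tuple(sorted(h)) for r, h in truth.items()}
                    obs[role] = bad
                    if all(a == REF for g in obs.values() for a in g):
                        continue
                    cls = classify_corrupted(obs, sm, sp)
                    local[side][0] += cls is not None
                    local[side][1] += 1
        else:
            slots = [(r, i) for r in ROLES for i in (0, 1)]
            for (r1, i1), (r2, i2) in combinations(slots, 2):
                if r1 == r2:
                    continue
                haps = {r: list(h) for r, h in truth.items()}
                haps[r1][i1] ^= 1
                haps[r2][i2] ^= 1
                obs = {r: tuple(sorted(h)) for r, h in haps.items()}
                if all(a == REF for g in obs.values() for a in g):
                    continue
                cls = classify_corrupted(obs, sm, sp)
                if r1 in CHILDREN and r2 in CHILDREN:
                    side = "child"
                elif r1 in PARENTS and r2 in PARENTS:
                    side = "parent"
                else:
                    continue
                local[side][0] += cls is not None
                local[side][1] += 1
        fracs = {}
        for side in ("child", "parent"):
            det, tot = local[side]
            if tot:
                num[side] += w * det / tot
                den[side] += w
                fracs[side] = det / tot
        per_config[config] = fracs
    return DetectabilityTable(
        detect_children=num["child"] / den["child"],
        detect_parents=num["parent"] / den["parent"],
        per_config=per_config,
    )


# ---------------------------------------------------------------------------
# Regional rates and concordance
# ---------------------------------------------------------------------------

def regional_error_rate(sites: list[QuartetSite], regions: RegionSet,
                        n_genomes: int = 4,
                        detectable_fraction: float | None = None) -> float:
    """Detected errors per base per haploid genome within labeled regions.

    When ``detectable_fraction`` is given, the count is scaled by 1/d to
    estimate total (detected plus undetected) errors.
    """
    length = regions.total_length()
    if length == 0:
        raise ValueError("empty region set")
    n_err = sum(1 for s in sites
                if s.error_class is not None and regions.contains(s.chrom, s.pos - 1))
    rate = n_err / (length * n_genomes)
    if detectable_fraction is not None:
        rate /= detectable_fraction
    return rate


def concordance_report(calls_a: dict, calls_b: dict) -> dict:
    """Genotype concordance over positions fully called in both sets.

    ``calls_a`` / ``calls_b`` map position keys to unordered allele pairs.
    """
    shared = [k for k in calls_a if k in calls_b]
    if not shared:
        raise ValueError("no overlapping positions between call sets")
    n_conc = sum(1 for k in shared
                 if tuple(sorted(calls_a[k])) == tuple(sorted(calls_b[k])))
    n_both = len(shared)
    return {
        "n_both": n_both,
        "n_concordant": n_conc,
        "n_discordant": n_both - n_conc,
        "pct_concordant": 100.0 * n_conc / n_both,
        "pct_discordant": 100.0 * (n_both - n_conc) / n_both,
    }
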