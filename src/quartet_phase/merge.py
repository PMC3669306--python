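"""Integration of transmission, physical and population phasing.

Fragment-based (physical) phasing links heterozygous sites co-observed on
one DNA fragment into phase sets; a phase set containing at least one
transmission-phased site propagates its orientation to quadruple-
heterozygous sites that transmission cannot resolve. Externally produced
per-trio population phasing fills what remains and imputes error/uncalled
positions. Precedence is strict: transmission > physical > population; a
later tier never flips an earlier tier's orientation, and disagreements are
counted, flagged and kept on the earlier tier's side.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .blocks import BlockMap, InheritanceBlock
from .model import ALT, CHILDREN, ROLES, Genotype, QuartetSite

SiteKey = tuple[str, int]


@dataclass(slots=True)
class PhaseFragment:
    """Allele observations from one sequenced DNA fragment."""

    fragment_id: str
    sample: str
    observations: list[tuple[SiteKey, int]]

    def het_observations(self, het_keys: set[SiteKey]) -> list[tuple[SiteKey, int]]:
        return [(k, a) for k, a in self.observations if k in het_keys]


@dataclass(slots=True)
class PhaseSet:
    """A connected component of fragment-linked heterozygous sites.

    ``orientation[key]`` is the allele carried by the set's arbitrary
    reference homolog at that site; the other homolog carries the
    complement. Only relative orientation is meaningful.
    """

    set_id: str
    sample: str
    orientation: dict[SiteKey, int]

    @property
    def n_sites(self) -> int:
        return len(self.orientation)

    @property
    def span(self) -> int:
        pos = [p for _, p in self.orientation]
        return max(pos) - min(pos)

    def chrom(self) -> str:
        return next(iter(self.orientation))[0]


def build_phase_sets(fragments: list[PhaseFragment],
                     het_keys: set[SiteKey]) -> list[PhaseSet]:
    """Connected components over sites sharing a fragment.

    Adjacent observations within a fragment vote for the relative
    orientation (parity) of the pair they link; ties drop the edge, as does
    any cycle conflict (the component is split at the conflicting edge).
    """
    by_sample: dict[str, list[PhaseFragment]] = {}
    for f in fragments:
        by_sample.setdefault(f.sample, []).append(f)
    out: list[PhaseSet] = []
    for sample, frags in sorted(by_sample.items()):
        votes: dict[tuple[SiteKey, SiteKey], Counter] = {}
        for f in frags:
            obs = sorted(f.het_observations(het_keys), key=lambda o: o[0])
            for (k1, a1), (k2, a2) in zip(obs, obs[1:]):
                if k1[0] != k2[0]:
                    continue  # fragments never span chromosomes
                votes.setdefault((k1, k2), Counter())[a1 ^ a2] += 1
        graph = nx.Graph()
        for (k1, k2), counter in votes.items():
            graph.add_nodes_from((k1, k2))
            (top, n_top), *rest = counter.most_common()
            if rest and rest[0][1] == n_top:
                continue  # tied votes: drop the edge, keep the singletons
            graph.add_edge(k1, k2, parity=top)
        while True:
            conflict = None
            orientations: dict[SiteKey, int] = {}
            for comp in nx.connected_components(graph):
                root = min(comp)
                orient = {root: 0}
                for u, v in nx.bfs_edges(graph, root):
                    orient[v] = orient[u] ^ graph[u][v]["parity"]
                for u, v, data in graph.subgraph(comp).edges(data=True):
                    if orient[u] ^ orient[v] != data["parity"]:
                        conflict = (u, v)
                        break
                if conflict:
                    break
                orientations.update(orient)
            if conflict is None:
                break
            graph.remove_edge(*conflict)
        for i, comp in enumerate(sorted(nx.connected_components(graph), key=min)):
            root = min(comp)
            orient = {root: 0}
            for u, v in nx.bfs_edges(graph, root):
                orient[v] = orient[u] ^ graph[u][v]["parity"]
            out.append(PhaseSet(f"{sample}_ps{i}", sample, orient))
    return out


@dataclass(slots=True)
class PhysicalIntegration:
    n_phased: int = 0
    n_divergent: int = 0   # transmission-phased sites disagreeing with the set


def integrate_physical(sites: list[QuartetSite], phase_sets: list[PhaseSet],
                       blocks: BlockMap | None = None) -> PhysicalIntegration:
    """Phase quad-het sites from phase sets anchored by transmission.

    For each phase set the orientation relative to the sample's first
    homolog (maternal for children, transmitted-to-child1 for parents) is
    taken by majority vote over the transmission-phased member sites;
    minority anchors are counted as divergences and keep their transmission
    phase. Unphased heterozygous members then inherit the majority
    orientation with ``phase_source="physical"``.

    A parent's transmission anchor switches physical homolog at every
    crossover in child 1's gamete, so for parents the vote and the
    propagation run separately within each inheritance block (``blocks``
    required to phase parents; junction sites are left alone).
    """
    index: dict[SiteKey, QuartetSite] = {s.key(): s for s in sites}
    result = PhysicalIntegration()
    for ps in phase_sets:
        is_parent = ps.sample in ("father", "mother")
        if is_parent and blocks is None:
            continue
        groups: dict[object, list[tuple[SiteKey, int]]] = {}
        for key, bit in ps.orientation.items():
            if key not in index:
                continue
            if is_parent:
                block = blocks.block_at(ps.sample, key[0], key[1])
                if block is None:
                    continue  # junction: anchor undefined there
                group = (block.chrom, block.start)
            else:
                group = key[0]  # children: one anchor per chromosome
            groups.setdefault(group, []).append((key, bit))
        for members in groups.values():
            votes = Counter()
            for key, bit in members:
                site = index[key]
                gt = site.gt(ps.sample)
                if site.source(ps.sample) == "transmission" and gt.is_het():
                    votes[0 if gt.ordered[0] == bit else 1] += 1
            if not votes:
                continue  # no transmission anchor: orientation unknowable
            (flip, n_top), *rest = votes.most_common()
            if rest and rest[0][1] == n_top:
                continue  # tied anchors: leave the group unused
            result.n_divergent += sum(n for o, n in votes.items() if o != flip)
            for key, bit in members:
                site = index[key]
                gt = site.gt(ps.sample)
                if site.source(ps.sample) != "unphased" or not gt.is_het():
                    continue
                first = bit if flip == 0 else ALT - bit
                site.genotypes[ps.sample] = gt.with_order(first, ALT - first)
                site.phase_source[ps.sample] = "physical"
                result.n_phased += 1
    return result


@dataclass(slots=True)
class PopulationIntegration:
    n_inconsistent: int = 0
    n_phased: int = 0
    n_imputed: int = 0


def integrate_population(sites: list[QuartetSite], trio_a: dict,
                         trio_b: dict) -> PopulationIntegration:
    """Fill remaining phases and impute errors from per-trio population calls.

    Positions where the two trios disagree on the parents' phase are dropped
    as population phasing errors. Remaining evidence phases still-unphased
    heterozygous genotypes (never overriding transmission or physical
    phases) and imputes genotypes at MIE/SCE/uncalled positions, which keep
    their error provenance.
    """
    result = PopulationIntegration()
    index: dict[SiteKey, QuartetSite] = {s.key(): s for s in sites}
    for key, site in index.items():
        rec_a = trio_a.get(key, {})
        rec_b = trio_b.get(key, {})
        inconsistent = any(
            r in rec_a and r in rec_b
            and rec_a[r]["ordered"] != rec_b[r]["ordered"]
            for r in ("father", "mother"))
        if inconsistent:
            result.n_inconsistent += 1
            continue
        merged = {**rec_a, **rec_b}
        for role, rec in merged.items():
            gt = site.gt(role)
            if gt.is_missing() or site.error_class is not None:
                site.genotypes[role] = Genotype.unphased(*rec["alleles"])
                if "imputed" not in site.notes:
                    site.notes.append("imputed")
                    result.n_imputed += 1
                site.phase_source[role] = "population"
                continue
            if site.source(role) != "unphased" or not gt.is_het():
                continue
            if tuple(sorted(rec["ordered"])) != gt.alleles:
                continue
            site.genotypes[role] = gt.with_order(*rec["ordered"])
            site.phase_source[role] = "population"
            result.n_phased += 1
    return result


# ---------------------------------------------------------------------------
# Parent-block orientation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class JunctionOrientation:
    parent: str
    chrom: str
    upstream: InheritanceBlock
    downstream: InheritanceBlock
    flip: bool | None          # does Transmitted-to-child1 change homolog?
    confidence: str | None     # "high" | "low" | None
    evidence: str | None       # "physical" | "population" | None


def phase_parent_blocks(blocks: BlockMap, phase_sets: list[PhaseSet],
                        population: dict, sites: list[QuartetSite],
                        flank_markers: int = 20,
                        min_informative: int = 5) -> list[JunctionOrientation]:
    """Orient adjacent parent blocks across their crossover junctions.

    Within a block a parent's phase is anchored to the homolog transmitted
    to child 1; a crossover in a child's gamete can make that anchor switch
    physical homolog. A phase set spanning the junction fixes the relative
    orientation with high confidence; otherwise population haplotypes on
    the two flanks are compared, with high confidence only when both flanks
    provide enough consistent heterozygous markers.
    """
    by_key: dict[SiteKey, QuartetSite] = {s.key(): s for s in sites}
    out: list[JunctionOrientation] = []
    for parent in ("father", "mother"):
        for up, down in blocks.adjacent_pairs(parent):
            jo = JunctionOrientation(parent, up.chrom, up, down, None, None, None)
            # physical evidence: a phase set with anchored hets in both blocks
            for ps in phase_sets:
                if ps.sample != parent:
                    continue
                rel = {True: Counter(), False: Counter()}  # upstream?
                for key, bit in ps.orientation.items():
                    site = by_key.get(key)
                    if site is None or site.source(parent) != "transmission":
                        continue
                    gt = site.gt(parent)
                    if not gt.is_het():
                        continue
                    pos0 = key[1] - 1
                    if key[0] == up.chrom and up.start <= pos0 < up.end:
                        rel[True][0 if gt.ordered[0] == bit else 1] += 1
                    elif key[0] == down.chrom and down.start <= pos0 < down.end:
                        rel[False][0 if gt.ordered[0] == bit else 1] += 1
                if rel[True] and rel[False]:
                    o_up = rel[True].most_common(1)[0][0]
                    o_down = rel[False].most_common(1)[0][0]
                    jo.flip = bool(o_up ^ o_down)
                    jo.confidence = "high"
                    jo.evidence = "physical"
                    break
            if jo.flip is None and population:
                side_votes = []
                for block, reverse in ((up, True), (down, False)):
                    votes: Counter = Counter()
                    keys = [k for k in by_key
                            if k[0] == block.chrom
                            and block.start <= k[1] - 1 < block.end]
                    keys.sort(key=lambda k: k[1], reverse=reverse)
                    for key in keys:
                        site = by_key[key]
                        gt = site.gt(parent)
                        rec = population.get(key, {}).get(parent)
                        if (rec is None or not gt.is_het()
                                or site.source(parent) != "transmission"):
                            continue
                        votes[0 if gt.ordered[0] == rec["ordered"][0] else 1] += 1
                        if sum(votes.values()) >= flank_markers:
                            break
                    side_votes.append(votes)
                v_up, v_down = side_votes
                if v_up and v_down:
                    o_up = v_up.most_common(1)[0][0]
                    o_down = v_down.most_common(1)[0][0]
                    jo.flip = bool(o_up ^ o_down)
                    jo.evidence = "population"
                    strong = all(
                        sum(v.values()) >= min_informative
                        and v.most_common(1)[0][1] >= 0.9 * sum(v.values())
                        for v in side_votes)
                    jo.confidence = "high" if strong else "low"
            out.append(jo)
    return out


def orient_block_chain(blocks: BlockMap, orientations: list[JunctionOrientation],
                       parent: str) -> dict[tuple[str, int], int | None]:
    """Cumulative homolog label per block: 0 = haplotype A, 1 = B.

    The first block of each chromosome defines label A as the homolog
    transmitted to child 1 there; the chain breaks (labels become None) at
    any unoriented junction.
    """
    labels: dict[tuple[str, int], int | None] = {}
    by_junction = {(o.upstream.chrom, o.upstream.start, o.downstream.start): o
                   for o in orientations if o.parent == parent}
    chrom = None
    current: int | None = None
    for i, block in enumerate(blocks.blocks(parent)):
        if block.chrom != chrom:
            chrom = block.chrom
            current = 0
            prev = block
            labels[(chrom, block.start)] = 0
            continue
        o = by_junction.get((chrom, prev.start, block.start))
        if o is None or o.flip is None or current is None:
            current = None
        else:
            current = current ^ int(o.flip)
        labels[(chrom, block.start)] = current
        prev = block
    return labels


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def phasing_rate_report(sites: list[QuartetSite]) -> pd.DataFrame:
    """Phasing rates per sample and for the quartet.

    A quartet-level site counts as phased when all four genotypes are
    phased; heterozygous columns use only each sample's heterozygous sites.
    """
    rows = []
    for role in ROLES:
        n = phased = het = het_phased = 0
        for s in sites:
            gt = s.gt(role)
            if gt.is_missing():
                continue
            n += 1
            phased += gt.phased
            if gt.is_het():
                het += 1
                het_phased += gt.phased
        rows.append({
            "sample": role, "n_sites": n,
            "phased": phased, "phased_pct": 100.0 * phased / n if n else 0.0,
            "unphased": n - phased,
            "het": het, "het_phased": het_phased,
            "het_phased_pct": 100.0 * het_phased / het if het else 0.0,
            "het_unphased_pct": 100.0 * (het - het_phased) / het if het else 0.0,
        })
    full = [s for s in sites if s.fully_called()]
    n = len(full)
    phased = sum(all(s.gt(r).phased for r in ROLES) for s in full)
    rows.append({
        "sample": "quartet", "n_sites": n, "phased": phased,
        "phased_pct": 100.0 * phased / n if n else 0.0,
        "unphased": n - phased,
        "het": sum(any(s.gt(r).is_het() for r in ROLES) for s in full),
        "het_phased": None, "het_phased_pct": None, "het_unphased_pct": None,
    })
    return pd.DataFrame(rows).set_index("sample")


def phase_set_stats(phase_sets: list[PhaseSet]) -> dict[str, int]:
    """N10 and N50 of phase-set spans.

    Nx is the span of the set at which the cumulative span of sets, sorted
    by decreasing span, first reaches x% of the total span.
    """
    spans = sorted((ps.span for ps in phase_sets), reverse=True)
    if not spans or sum(spans) == 0:
        raise ValueError("no phase sets with positive span")
    total = sum(spans)
    out = {}
    for x in (10, 50):
        acc = 0
        for s in spans:
            acc += s
            if acc >= total * x / 100.0:
                out[f"N{x}"] = s
                break
    return out


def annotate_parental_origin(sites: list[QuartetSite],
                             chain_labels: dict[str, dict] | None = None) -> int:
    """Write the parental-origin (AA) annotation on every phased genotype.

    Children: ``M=<maternal allele>|P=<paternal allele>``. Parents (when the
    block chain is oriented there): ``A=<allele>|B=<allele>`` in
    grandparental-haplotype labels. (Colons and commas are reserved
    characters in VCF sample fields.) Returns the number of annotations set.
    """
    n = 0
    for s in sites:
        for child in CHILDREN:
            gt = s.gt(child)
            if gt.phased:
                s.parental_origin[child] = f"M={gt.a}|P={gt.b}"
                n += 1
        for parent in ("father", "mother"):
            gt = s.gt(parent)
            if not gt.phased or chain_labels is None:
                continue
            labels = chain_labels.get(parent)
            if not labels:
                continue
            lab = None
            for (chrom, start), value in labels.items():
                if chrom == s.chrom and start <= s.pos - 1:
                    lab = value  # labels iterate in block order per chrom
            if lab is None:
                continue
            a_allele, b_allele = (gt.a, gt.b) if lab == 0 else (gt.b, gt.a)
            s.parental_origin[parent] = f"A={a_allele}|B={b_allele}"
            n += 1
    return n


def classify_double_het(gene_intervals: list[tuple[str, int, int, str]],
                        sites: list[QuartetSite], sample: str) -> dict[str, str]:
    """cis/trans classification of multi-het genes for one sample.

    Genes with >= 2 heterozygous sites get "cis" when every alternate allele
    sits on the same homolog, "trans" when they are split, and
    "undetermined" when any contributing site is unphased.
    """
    out: dict[str, str] = {}
    for chrom, start, end, name in gene_intervals:
        hets = [s for s in sites
                if s.chrom == chrom and start <= s.pos - 1 < end
                and s.gt(sample).is_het()]
        if len(hets) < 2:
            continue
        if any(not s.gt(sample).phased for s in hets):
            out[name] = "undetermined"
            continue
        sides = {0 if s.gt(sample).ordered[0] == ALT else 1 for s in hets}
        out[name] = "cis" if len(sides) == 1 else "trans"
    return out
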