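"""Inheritance-state comparison tracks, block segmentation and crossovers.

Each phased, informative site contributes a signed marker per parent: +1
when both children inherited the same parental homolog there, -1 when they
inherited different ones. Runs of consistent sign delimit the blocks of
inheritance; the junction between two adjacent blocks contains a crossover
in one of the two children's gametes.

Segmentation is an exact two-state dynamic program that minimizes
(number of discordant markers) + r x (number of state switches): a switch is
only worth declaring when at least r opposite markers back it, so isolated
discordant markers (SCE candidates) do not break blocks, while a sustained
sign change (a real crossover) does. Runs shorter than ``min_markers`` are
absorbed into their neighbors afterwards.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from statistics import mean, median

from .model import CHILDREN, DIFFERENT, SAME, QuartetSite

PARENT_ALLELE_INDEX = {"mother": 0, "father": 1}  # child ordered = (maternal, paternal)


@dataclass(slots=True)
class IslandParams:
    """Two-threshold island-finder parameters."""

    min_opposite_run: int = 10   # r: opposite markers needed to open a block
    min_markers: int = 20        # m: runs shorter than this are absorbed
    max_discordant_fraction: float = 0.1  # f: QC flag threshold per run


@dataclass(slots=True)
class ComparisonTrack:
    parent: str
    chrom: str
    positions: list[int]          # 1-based, strictly increasing
    values: list[int]             # +1 / -1

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("marker positions must strictly increase")


@dataclass(slots=True)
class InheritanceBlock:
    parent: str
    chrom: str
    start: int                    # 0-based half-open, covering its markers
    end: int
    state: str                    # SAME | DIFFERENT
    n_markers: int
    n_discordant: int

    @property
    def discordant_fraction(self) -> float:
        return self.n_discordant / self.n_markers


@dataclass(slots=True)
class Crossover:
    parent: str
    chrom: str
    start: int                    # junction: 0-based half-open between the
    end: int                      # flanking markers (both excluded)

    @property
    def gap_bp(self) -> int:
        """Distance between the two phased markers flanking the junction."""
        return self.end - self.start + 1


def build_comparison_track(sites: list[QuartetSite], parent: str,
                           chrom: str) -> ComparisonTrack:
    """One +-1 marker per informative site of a chromosome.

    A site is informative for a parent when the parent is heterozygous and
    both children carry a transmission-phased ordered genotype (so the allele
    each child received from that parent, hence the homolog, is known).
    """
    idx = PARENT_ALLELE_INDEX[parent]
    positions: list[int] = []
    values: list[int] = []
    for s in sites:
        if s.chrom != chrom or not s.gt(parent).is_het():
            continue
        if any(not s.gt(c).phased or s.source(c) != "transmission" for c in CHILDREN):
            continue
        a1 = s.gt("child1").ordered[idx]
        a2 = s.gt("child2").ordered[idx]
        positions.append(s.pos)
        values.append(1 if a1 == a2 else -1)
    return ComparisonTrack(parent, chrom, positions, values)


@dataclass(slots=True)
class StateRun:
    start: int                    # marker indices, half-open
    stop: int
    state: int                    # +1 / -1
    n_discordant: int = 0
    qc_flag: bool = False

    @property
    def n_markers(self) -> int:
        return self.stop - self.start


def segment_islands(values: list[int],
                    params: IslandParams | None = None) -> list[StateRun]:
    """Partition a signed marker sequence into maximal state runs.

    Exact minimization of (#discordant) + r x (#switches) by dynamic
    programming over the two states, with ties broken in favor of staying in
    the current state (fewest switches) and, for the final state, in favor
    of the sign of the last marker. Runs shorter than ``min_markers`` are
    then absorbed into their neighbors; runs whose discordant fraction
    exceeds ``max_discordant_fraction`` are QC-flagged.
    """
    params = params or IslandParams()
    n = len(values)
    if n == 0:
        raise ValueError("need at least one marker")
    r = params.min_opposite_run
    # cost[s] = best cost ending in state s; choice[i][s] = previous state
    cost = {1: float(values[0] != 1), -1: float(values[0] != -1)}
    choice = [{1: 1, -1: -1}]
    for i in range(1, n):
        new_cost = {}
        prev = {}
        for s in (1, -1):
            stay = cost[s]
            switch = cost[-s] + r
            if stay <= switch:       # tie -> stay
                new_cost[s] = stay + (values[i] != s)
                prev[s] = s
            else:
                new_cost[s] = switch + (values[i] != s)
                prev[s] = -s
        cost = new_cost
        choice.append(prev)
    last = values[-1]
    if cost[last] <= cost[-last]:    # tie -> agree with the final marker
        state = last
    else:
        state = -last
    states = [state]
    for i in range(n - 1, 0, -1):
        state = choice[i][state]
        states.append(state)
    states.reverse()

    runs: list[StateRun] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[start]:
            runs.append(StateRun(start, i, states[start]))
            start = i
    # absorb short runs into neighbors (repeatedly, shortest first)
    while len(runs) > 1:
        shortest = min(runs, key=lambda x: x.n_markers)
        if shortest.n_markers >= params.min_markers:
            break
        i = runs.index(shortest)
        if 0 < i < len(runs) - 1:
            merged = StateRun(runs[i - 1].start, runs[i + 1].stop, runs[i - 1].state)
            runs[i - 1:i + 2] = [merged]
        elif i == 0:
            runs[1].start = runs[0].start
            del runs[0]
        else:
            runs[-2].stop = runs[-1].stop
            del runs[-1]
    for run in runs:
        run.n_discordant = sum(1 for v in values[run.start:run.stop] if v != run.state)
        run.qc_flag = (run.n_discordant / run.n_markers
                       > params.max_discordant_fraction)
    return runs


def call_inheritance_blocks(track: ComparisonTrack,
                            params: IslandParams | None = None
                            ) -> tuple[list[InheritanceBlock], list[Crossover]]:
    """Segment one chromosome track into blocks and call the crossovers.

    Blocks cover [first marker, last marker] of their run in 0-based
    half-open coordinates; chromosome ends remain open. One crossover is
    emitted per adjacent block pair, its junction being the open interval
    between the last marker of the upstream block and the first marker of
    the downstream one.
    """
    if not track.positions:
        return [], []
    runs = segment_islands(track.values, params)
    blocks = []
    for run in runs:
        blocks.append(InheritanceBlock(
            parent=track.parent, chrom=track.chrom,
            start=track.positions[run.start] - 1,
            end=track.positions[run.stop - 1],
            state=SAME if run.state == 1 else DIFFERENT,
            n_markers=run.n_markers, n_discordant=run.n_discordant))
    crossovers = []
    for up, down in zip(blocks, blocks[1:]):
        crossovers.append(Crossover(track.parent, track.chrom,
                                    start=up.end, end=down.start))
    return blocks, crossovers


def refine_block_edges(track: ComparisonTrack, extra: ComparisonTrack,
                       params: IslandParams | None = None
                       ) -> tuple[list[InheritanceBlock], list[Crossover]]:
    """Re-segment on the union of the original and newly phased markers.

    The extra markers typically come from triple-heterozygous sites phased
    with the preliminary blocks; adding them can only tighten (never widen)
    the junction gaps.
    """
    if (extra.parent, extra.chrom) != (track.parent, track.chrom):
        raise ValueError("tracks must describe the same parent and chromosome")
    merged = sorted(set(zip(track.positions, track.values))
                    | set(zip(extra.positions, extra.values)))
    union = ComparisonTrack(track.parent, track.chrom,
                            [p for p, _ in merged], [v for _, v in merged])
    return call_inheritance_blocks(union, params)


def crossover_summary(crossovers: list[Crossover], n_chromosomes: int,
                      n_gametes: int = 2) -> dict:
    """Per-parent counts, per-chromosome-per-gamete means and junction gaps."""
    out: dict = {}
    for parent in ("mother", "father"):
        xs = [c for c in crossovers if c.parent == parent]
        gaps = [c.gap_bp for c in xs]
        out[parent] = {
            "count": len(xs),
            "per_chromosome_per_gamete": len(xs) / (n_gametes * n_chromosomes),
            "median_gap_bp": median(gaps) if gaps else None,
            "mean_gap_bp": mean(gaps) if gaps else None,
        }
    return out


class BlockMap:
    """Position-indexed lookup of inheritance-block states per parent."""

    def __init__(self, blocks: list[InheritanceBlock] | None = None):
        self._by_key: dict[tuple[str, str], list[InheritanceBlock]] = {}
        for b in blocks or []:
            self._by_key.setdefault((b.parent, b.chrom), []).append(b)
        for key, bs in self._by_key.items():
            bs.sort(key=lambda b: b.start)
            self._by_key[key] = bs

    def block_at(self, parent: str, chrom: str, pos: int) -> InheritanceBlock | None:
        """Block containing a 1-based position; None in junctions or gaps."""
        bs = self._by_key.get((parent, chrom))
        if not bs:
            return None
        pos0 = pos - 1
        starts = [b.start for b in bs]
        i = bisect_right(starts, pos0) - 1
        if i >= 0 and bs[i].start <= pos0 < bs[i].end:
            return bs[i]
        return None

    def state_at(self, parent: str, chrom: str, pos: int) -> str | None:
        """Block state at a 1-based position; None in junctions or gaps."""
        block = self.block_at(parent, chrom, pos)
        return block.state if block else None

    def blocks(self, parent: str | None = None) -> list[InheritanceBlock]:
        out = []
        for (p, _), bs in sorted(self._by_key.items()):
            if parent is None or p == parent:
                out.extend(bs)
        return out

    def adjacent_pairs(self, parent: str) -> list[tuple[InheritanceBlock, InheritanceBlock]]:
        pairs = []
        for (p, _), bs in sorted(self._by_key.items()):
            if p != parent:
                continue
            pairs.extend(zip(bs, bs[1:]))
        return pairs


class ConstantBlockMap(BlockMap):
    """A block map returning fixed states everywhere (handy for enumeration)."""

    def __init__(self, maternal_state: str, paternal_state: str):
        super().__init__([])
        self._states = {"mother": maternal_state, "father": paternal_state}

    def state_at(self, parent: str, chrom: str, pos: int) -> str | None:
        return self._states[parent]
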