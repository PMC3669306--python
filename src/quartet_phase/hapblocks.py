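"""Haplotype-block calling from one phased sample's SNP-density tracks.

A phased genome exposes its haplotype structure directly: plotting
homozygous SNPs (1|1) and heterozygous SNPs per homolog (0|1, 1|0) as three
tracks reveals density islands. Regions are classified by which tracks have
islands: one track gives that class, two or more give a mixed block, none a
SNP-poor block; the classes tile each chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ALT, REF, QuartetSite

TRACKS = ("1|1", "0|1", "1|0")


@dataclass(slots=True)
class TrackParams:
    window: int = 10_000       # bp
    min_snps: int = 5          # per window to open an island
    merge_gap: int = 20_000    # bp between islands to merge


@dataclass(slots=True)
class GenotypeTracks:
    sample: str
    positions: dict[str, dict[str, list[int]]]  # chrom -> track -> positions
    n_unphased_het: int = 0


@dataclass(slots=True)
class HaplotypeBlockCall:
    chrom: str
    start: int                 # 0-based half-open
    end: int
    block_class: str           # "1|1" | "0|1" | "1|0" | "mixed" | "SNP-poor"
    n_snps: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def snp_density_per_kb(self) -> float:
        return 1000.0 * self.n_snps / self.length


def build_genotype_tracks(sites: list[QuartetSite], sample: str) -> GenotypeTracks:
    """Assign every phased variant of a sample to exactly one track.

    Hom-ALT genotypes go to 1|1; phased heterozygotes to 0|1 or 1|0 by the
    homolog carrying the alternate allele. Unphased heterozygotes are
    excluded and counted; hom-REF and missing genotypes carry no variant for
    this sample.
    """
    tracks = GenotypeTracks(sample, {})
    for s in sites:
        gt = s.gt(sample)
        if gt.is_missing() or gt.alleles == (REF, REF):
            continue
        if gt.is_het():
            if not gt.phased:
                tracks.n_unphased_het += 1
                continue
            name = "0|1" if gt.ordered[1] == ALT else "1|0"
        elif gt.alleles == (ALT, ALT):
            name = "1|1"
        else:
            continue  # hemizygous or non-standard alleles
        tracks.positions.setdefault(s.chrom, {t: [] for t in TRACKS})[name].append(s.pos)
    return tracks


def _islands(positions: list[int], length: int, params: TrackParams
             ) -> list[tuple[int, int]]:
    """Density islands: windows holding >= min_snps, merged across small gaps."""
    if not positions:
        return []
    w = params.window
    n_bins = (length + w - 1) // w
    counts = np.bincount(np.asarray(positions, dtype=np.int64) // w,
                         minlength=n_bins)
    hot = np.flatnonzero(counts >= params.min_snps)
    if hot.size == 0:
        return []
    gap_bins = params.merge_gap // w
    islands = []
    run_start = hot[0]
    prev = hot[0]
    for b in hot[1:]:
        if b - prev > gap_bins + 1:
            islands.append((int(run_start * w), int(min((prev + 1) * w, length))))
            run_start = b
        prev = b
    islands.append((int(run_start * w), int(min((prev + 1) * w, length))))
    return islands


def call_haplotype_blocks(tracks: GenotypeTracks | dict,
                          chrom_lengths: dict[str, int],
                          params: TrackParams | None = None
                          ) -> list[HaplotypeBlockCall]:
    """Classify each chromosome into haplotype-block classes.

    ``tracks`` is a :class:`GenotypeTracks` or a plain
    ``{chrom: {track: positions}}`` mapping. Island calls per track are
    intersected: regions covered by exactly one track's islands take that
    class, by two or more "mixed", by none "SNP-poor". Every SNP is counted
    in the block containing it.
    """
    params = params or TrackParams()
    positions = tracks.positions if isinstance(tracks, GenotypeTracks) else tracks
    calls: list[HaplotypeBlockCall] = []
    for chrom, length in sorted(chrom_lengths.items()):
        per_track = positions.get(chrom, {t: [] for t in TRACKS})
        islands = {t: _islands(sorted(per_track.get(t, [])), length, params)
                   for t in TRACKS}
        edges = {0, length}
        for ivs in islands.values():
            for s, e in ivs:
                edges.update((s, e))
        cuts = sorted(edges)
        all_pos = np.sort(np.concatenate(
            [np.asarray(per_track.get(t, []), dtype=np.int64) for t in TRACKS]))
        prev_call: HaplotypeBlockCall | None = None
        for s, e in zip(cuts, cuts[1:]):
            covering = [t for t, ivs in islands.items()
                        if any(a <= s and e <= b for a, b in ivs)]
            if len(covering) == 0:
                cls = "SNP-poor"
            elif len(covering) == 1:
                cls = covering[0]
            else:
                cls = "mixed"
            n_snps = int(np.searchsorted(all_pos, e, side="right")
                         - np.searchsorted(all_pos, s + 1, side="left"))
            if prev_call is not None and prev_call.block_class == cls:
                prev_call.end = e
                prev_call.n_snps += n_snps
            else:
                prev_call = HaplotypeBlockCall(chrom, s, e, cls, n_snps)
                calls.append(prev_call)
    return calls


def haplotype_block_stats(calls: list[HaplotypeBlockCall]) -> pd.DataFrame:
    """Per-class summary: counts, lengths, genome share and SNP density."""
    if not calls:
        raise ValueError("no block calls")
    total_len = sum(c.length for c in calls)
    rows = []
    classes = ["0|1", "1|0", "1|1", "mixed", "SNP-poor"]
    for cls in classes + ["genome"]:
        sel = calls if cls == "genome" else [c for c in calls if c.block_class == cls]
        n = len(sel)
        snps = sum(c.n_snps for c in sel)
        length = sum(c.length for c in sel)
        rows.append({
            "class": cls, "n_blocks": n, "n_snps": snps,
            "total_length_bp": length,
            "mean_length_bp": length / n if n else 0.0,
            "pct_genome": 100.0 * length / total_len,
            "snp_density_per_kb": 1000.0 * snps / length if length else 0.0,
        })
    return pd.DataFrame(rows).set_index("class")
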