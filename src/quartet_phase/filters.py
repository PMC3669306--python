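"""Variant filters: read-depth mask, recalibration pass-through, PL filter.

The filter chain mirrors the order used on the real quartet: first a
read-depth mask removing regions with abnormally high coverage in *all four*
members (collapsed repeats absent from the reference, a major source of
clustered errors), then the caller's recalibration FILTER column, then a
genotype-likelihood (PL) confidence filter. Each stage reports how many
sites and how many classified errors it removed, so filter efficiency
(errors removed / sites removed) can be tracked per stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ROLES, QuartetSite, RegionSet


@dataclass(slots=True)
class CoverageTrack:
    """Binned read counts for one sample."""

    role: str
    bin_width: int
    counts: dict[str, np.ndarray]  # chrom -> per-bin read counts

    def median(self) -> float:
        """Genome-wide median bin count for this sample."""
        return float(np.median(np.concatenate(list(self.counts.values()))))


def build_read_depth_mask(tracks: dict[str, CoverageTrack],
                          multiplier: float = 2.0,
                          gap_bins: int = 1) -> tuple[RegionSet, float]:
    """Mask bins where every member's depth is >= multiplier x its median.

    Flagged bins closer than ``gap_bins`` bins apart merge into one
    interval. Returns the mask and the fraction of the binned genome masked.
    """
    if set(tracks) != set(ROLES):
        raise ValueError("need one coverage track per pedigree role")
    widths = {t.bin_width for t in tracks.values()}
    if len(widths) != 1:
        raise ValueError("all coverage tracks must share one bin width")
    bin_width = widths.pop()
    chrom_sets = [set(t.counts) for t in tracks.values()]
    if any(cs != chrom_sets[0] for cs in chrom_sets):
        raise ValueError("all coverage tracks must cover the same chromosomes")
    thresholds = {role: multiplier * t.median() for role, t in tracks.items()}
    mask = RegionSet(label="high_read_depth")
    total_bins = 0
    masked_bins = 0
    for chrom in sorted(chrom_sets[0]):
        flagged = np.ones_like(tracks["father"].counts[chrom], dtype=bool)
        for role, t in tracks.items():
            flagged &= t.counts[chrom] >= thresholds[role]
        total_bins += flagged.size
        masked_bins += int(flagged.sum())
        idx = np.flatnonzero(flagged)
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i - prev > gap_bins + 1:
                mask.add(chrom, run_start * bin_width, (prev + 1) * bin_width)
                run_start = i
            prev = i
        mask.add(chrom, run_start * bin_width, (prev + 1) * bin_width)
    mask.normalize()
    fraction = masked_bins / total_bins if total_bins else 0.0
    return mask, fraction


@dataclass(slots=True)
class FilterOutcome:
    kept: list[QuartetSite]
    removed: list[QuartetSite]
    removed_by_class: dict[str, int] = field(default_factory=dict)

    @property
    def n_errors_removed(self) -> int:
        return sum(v for k, v in self.removed_by_class.items() if k in ("MIE", "SCE"))


def _tally(removed: list[QuartetSite]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in removed:
        key = s.error_class or "clean"
        out[key] = out.get(key, 0) + 1
    return out


def apply_region_filter(sites: list[QuartetSite], mask: RegionSet) -> FilterOutcome:
    """Remove sites whose (0-based) position falls inside the mask."""
    kept, removed = [], []
    for s in sites:
        (removed if mask.contains(s.chrom, s.pos - 1) else kept).append(s)
    return FilterOutcome(kept, removed, _tally(removed))


def recalibration_filter(sites: list[QuartetSite],
                         passing: tuple[str, ...] = ("PASS",)) -> FilterOutcome:
    """Pass-through of the caller's FILTER column (recalibration tier)."""
    kept, removed = [], []
    for s in sites:
        (kept if any(f in passing for f in s.filter_status) else removed).append(s)
    return FilterOutcome(kept, removed, _tally(removed))


def genotype_margin(pl: tuple[int, int, int]) -> int:
    """Confidence margin of the called genotype: the second-smallest PL.

    PL values are phred-scaled likelihood ratios with 0 at the called
    genotype; the second-smallest entry is how much less likely the best
    alternative is.
    """
    return sorted(pl)[1]


def pl_filter(sites: list[QuartetSite], min_pl: int = 20) -> FilterOutcome:
    """Remove low-confidence and partially called sites.

    A site is removed when any member's genotype margin is below ``min_pl``
    or any member is uncalled. Members without PL values are exempt from the
    margin test (but not from the called-genotype requirement).
    """
    kept, removed = [], []
    for s in sites:
        bad = not s.fully_called()
        if not bad:
            for role in ROLES:
                pl = s.pl.get(role)
                if pl is not None and genotype_margin(pl) < min_pl:
                    bad = True
                    break
        (removed if bad else kept).append(s)
    return FilterOutcome(kept, removed, _tally(removed))


def filter_efficiency(n_errors_removed: int, n_sites_removed: int) -> float:
    """Errors removed per site removed."""
    if n_sites_removed <= 0:
        raise ValueError("no sites removed: efficiency undefined")
    return n_errors_removed / n_sites_removed
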