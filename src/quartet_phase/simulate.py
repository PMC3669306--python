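"""Truth-annotated synthetic quartets exercising every pipeline stage.

The generator models what the pipeline consumes, not reads or bases:
parental haplotypes are mosaics of ancestry-density classes (SNP-poor,
single-haplotype and mixed segments with the observed genome fractions and
SNP densities), children are recombinant gametes with Poisson crossovers at
the female/male rates, and observation adds genotype miscalls, missing
calls, a depth-scaled PL margin model, heterozygous deletions (hemizygous
miscalls), high-read-depth repeat regions, phase fragments and a surrogate
population (trio-phased) call set with Markov switch errors. Every
perturbation is recorded in the truth object so tests can compare any
pipeline output against its generating value.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockMap, InheritanceBlock
from .filters import CoverageTrack
from .merge import PhaseFragment
from .model import (ALT, CHILDREN, DIFFERENT, MISSING, REF, ROLES, SAME,
                    Genotype, QuartetSite)
from .sv import SVCall

_PARENT_OF_SLOT = ("mother", "father")


def _default_chromosomes() -> dict[str, int]:
    return {"chr1": 30_000_000, "chr2": 20_000_000}


@dataclass
class SimConfig:
    """Study conditions for the synthetic quartet.

    Densities and fractions follow the haplotype-block structure of a
    sequenced human genome (SNP-poor 0.36/kb over ~36% of the genome,
    single-haplotype ~1.35/kb over ~45.6%, mixed 2.15/kb over ~18.4%, mean
    segment length 58.5 kb); crossover rates are per chromosome per gamete
    (female 1.85, male 1.27); insert sizes mirror the three sequencing
    libraries (300 bp, 600 bp, 2.5 kb).
    """

    chromosome_lengths: dict[str, int] = field(default_factory=_default_chromosomes)
    block_length_mean: float = 58_500.0
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "snp_poor": 0.36, "single": 0.4565, "mixed": 0.1835})
    class_densities_per_kb: dict[str, float] = field(default_factory=lambda: {
        "snp_poor": 0.36, "single": 1.35, "mixed": 2.15})
    class_alt_prob: dict[str, float] = field(default_factory=lambda: {
        "snp_poor": 0.15, "single": 0.35, "mixed": 0.5})
    maternal_crossover_rate: float = 1.85
    paternal_crossover_rate: float = 1.27
    quad_het_fraction: float = 0.04
    miscall_rate: float = 1e-3        # per sequenced allele
    missing_rate: float = 5e-3        # per member-site
    mean_depth: float = 30.0
    coverage_bin_width: int = 500
    n_high_depth_regions: int = 0
    high_depth_length: int = 10_000
    n_deletions: int = 0
    deletion_length: int = 20_000
    fragment_insert_sizes: tuple[int, ...] = (300, 600, 2500)
    fragment_coverage: float = 0.0    # mean fragments covering a base
    fragment_error_rate: float = 0.0  # per allele observation
    population_switch_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("quad_het_fraction", "miscall_rate", "missing_rate",
                     "fragment_error_rate", "population_switch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


@dataclass(slots=True)
class SiteTruth:
    chrom: str
    pos: int
    haps: tuple[int, int, int, int]        # (m0, m1, f0, f1)
    hom_choice: tuple[int, int, int, int]  # (c1<-m, c1<-f, c2<-m, c2<-f)
    seg_class: str

    def ordered(self, role: str) -> tuple[int, int]:
        """Truth phase: children Maternal|Paternal, parents hap0|hap1."""
        m0, m1, f0, f1 = self.haps
        a1, b1, a2, b2 = self.hom_choice
        if role == "mother":
            return (m0, m1)
        if role == "father":
            return (f0, f1)
        m = (m0, m1)
        f = (f0, f1)
        if role == "child1":
            return (m[a1], f[b1])
        return (m[a2], f[b2])

    def anchored_parent(self, parent: str) -> tuple[int, int]:
        """Parent phase anchored Transmitted-to-child1|Other."""
        m0, m1, f0, f1 = self.haps
        a1, b1, _, _ = self.hom_choice
        if parent == "mother":
            return ((m0, m1)[a1], (m0, m1)[1 - a1])
        return ((f0, f1)[b1], (f0, f1)[1 - b1])

    def state(self, parent: str) -> str:
        a1, b1, a2, b2 = self.hom_choice
        if parent == "mother":
            return SAME if a1 == a2 else DIFFERENT
        return SAME if b1 == b2 else DIFFERENT

    def is_quad_het(self) -> bool:
        return all(self.ordered(r)[0] != self.ordered(r)[1] for r in ROLES)


@dataclass
class Deletion:
    sv: SVCall
    carrier_parent: str
    carrier_hap: int


@dataclass
class SimTruth:
    config: SimConfig
    site_truth: list[SiteTruth]
    transmission: dict[tuple[str, str, str], tuple[int, list[int]]]
    crossovers: list[tuple[str, str, str, int]]  # (child, parent, chrom, pos)
    errors: list[tuple[int, str, int, int, int]]  # (site, role, slot, old, new)
    missing: list[tuple[int, str]]
    deletions: list[Deletion]
    class_segments: list[tuple[str, int, int, str]]
    high_depth_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def homolog_at(self, child: str, parent: str, chrom: str, pos: int) -> int:
        start, breaks = self.transmission[(child, parent, chrom)]
        return start ^ (bisect_right(breaks, pos) & 1)

    def state_at(self, parent: str, chrom: str, pos: int) -> str:
        h1 = self.homolog_at("child1", parent, chrom, pos)
        h2 = self.homolog_at("child2", parent, chrom, pos)
        return SAME if h1 == h2 else DIFFERENT

    def block_map(self) -> BlockMap:
        """Exact inheritance blocks from the true transmission maps."""
        blocks = []
        for parent in ("mother", "father"):
            for chrom, length in self.config.chromosome_lengths.items():
                cuts = sorted({b for c in CHILDREN
                               for b in self.transmission[(c, parent, chrom)][1]})
                edges = [0, *cuts, length]
                for s, e in zip(edges, edges[1:]):
                    if e <= s:
                        continue
                    state = self.state_at(parent, chrom, s + 1)
                    blocks.append(InheritanceBlock(parent, chrom, s, e, state, 0, 0))
        return BlockMap(blocks)


@dataclass
class SimResult:
    truth: SimTruth
    sites: list[QuartetSite]
    coverage: dict[str, CoverageTrack]


def _draw_haps(rng: np.random.Generator, q: float) -> tuple[int, int, int, int]:
    while True:
        h = tuple(int(x) for x in rng.random(4) < q)
        if any(h):
            return h


def simulate_quartet(config: SimConfig | None = None,
                     seed: int | None = None) -> SimResult:
    """Generate a quartet: truth, observed call set and coverage tracks."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- transmission maps and crossovers ------------------------------------
    transmission: dict[tuple[str, str, str], tuple[int, list[int]]] = {}
    crossovers: list[tuple[str, str, str, int]] = []
    rates = {"mother": config.maternal_crossover_rate,
             "father": config.paternal_crossover_rate}
    for child in CHILDREN:
        for parent in ("mother", "father"):
            for chrom, length in config.chromosome_lengths.items():
                n_x = rng.poisson(rates[parent])
                breaks = sorted(int(p) for p in rng.integers(1, length, size=n_x))
                transmission[(child, parent, chrom)] = (int(rng.integers(2)), breaks)
                crossovers.extend((child, parent, chrom, b) for b in breaks)

    # --- ancestry-class segments and sites ------------------------------------
    classes = sorted(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    segments: list[tuple[str, int, int, str]] = []
    site_truth: list[SiteTruth] = []
    for chrom, length in config.chromosome_lengths.items():
        pos = 0
        while pos < length:
            seg_len = max(1000, int(rng.exponential(config.block_length_mean)))
            end = min(length, pos + seg_len)
            seg_class = classes[int(rng.choice(len(classes), p=probs))]
            segments.append((chrom, pos, end, seg_class))
            density = config.class_densities_per_kb[seg_class] / 1000.0
            n_sites = rng.poisson((end - pos) * density)
            positions = np.unique(rng.integers(pos + 1, end + 1, size=n_sites))
            q = config.class_alt_prob[seg_class]
            for p in positions:
                p = int(p)
                hom = tuple(transmission[(c, par, chrom)][0]
                            ^ (bisect_right(transmission[(c, par, chrom)][1], p) & 1)
                            for c in CHILDREN for par in ("mother", "father"))
                hom = (hom[0], hom[1], hom[2], hom[3])
                states_compatible = (hom[0] == hom[2]) == (hom[1] == hom[3])
                if states_compatible and rng.random() < config.quad_het_fraction:
                    m = (REF, ALT) if rng.random() < 0.5 else (ALT, REF)
                    f = [0, 0]
                    f[hom[1]] = ALT - m[hom[0]]  # make child1 heterozygous
                    f[1 - hom[1]] = ALT - f[hom[1]]
                    haps = (m[0], m[1], f[0], f[1])
                else:
                    haps = _draw_haps(rng, q)
                site_truth.append(SiteTruth(chrom, p, haps, hom, seg_class))
            pos = end
    site_truth.sort(key=lambda s: (s.chrom, s.pos))

    # --- deletions -------------------------------------------------------------
    deletions: list[Deletion] = []
    chrom_names = list(config.chromosome_lengths)
    chrom_weights = np.array([config.chromosome_lengths[c] for c in chrom_names],
                             dtype=float)
    chrom_weights /= chrom_weights.sum()
    for k in range(config.n_deletions):
        for _ in range(50):  # avoid crossover breakpoints inside the deletion
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_weights))]
            length = config.chromosome_lengths[chrom]
            start = int(rng.integers(0, max(1, length - config.deletion_length)))
            end = start + config.deletion_length
            carrier = "mother" if rng.random() < 0.5 else "father"
            if any(start < b <= end
                   for c in CHILDREN
                   for b in transmission[(c, carrier, chrom)][1]):
                continue
            if any(d.sv.chrom == chrom and d.sv.start < end and start < d.sv.end
                   for d in deletions):
                continue  # complex multi-deletion regions are out of scope
            hap = int(rng.integers(2))
            gts: dict[str, tuple[int, int] | None] = {
                carrier: (0, 1),
                ("father" if carrier == "mother" else "mother"): (0, 0),
            }
            for c in CHILDREN:
                start_h, breaks = transmission[(c, carrier, chrom)]
                inherited = start_h ^ (bisect_right(breaks, start + 1) & 1)
                gts[c] = (0, 1) if inherited == hap else (0, 0)
            deletions.append(Deletion(
                SVCall(chrom, start, end, "DEL", f"sim{k}", gts), carrier, hap))
            break

    def deleted_roles(st: SiteTruth) -> dict[str, int]:
        """Roles hemizygous at this site -> index of the deleted homolog."""
        out: dict[str, int] = {}
        for d in deletions:
            if d.sv.chrom != st.chrom or not (d.sv.start <= st.pos - 1 < d.sv.end):
                continue
            out[d.carrier_parent] = d.carrier_hap
            for ci, c in enumerate(CHILDREN):
                par_slot = 0 if d.carrier_parent == "mother" else 1
                if st.hom_choice[2 * ci + par_slot] == d.carrier_hap:
                    # the child's homolog from the carrier parent is deleted:
                    # index 0 = maternal, 1 = paternal in the child's ordering
                    out[c] = par_slot
        return out

    # --- observation: hemizygous masking, miscalls, missingness ---------------
    errors: list[tuple[int, str, int, int, int]] = []
    missing: list[tuple[int, str]] = []
    sites: list[QuartetSite] = []
    for i, st in enumerate(site_truth):
        observed = {r: list(st.ordered(r)) for r in ROLES}
        hemi = deleted_roles(st)
        for role, slot in hemi.items():
            observed[role][slot] = observed[role][1 - slot]  # only the
            # remaining homolog is sequenced: the call collapses to it
        erroneous: set[str] = set()
        if not hemi:  # keep the error registry a clean bijection
            for role in ROLES:
                for slot in (0, 1):
                    if rng.random() < config.miscall_rate:
                        old = observed[role][slot]
                        observed[role][slot] = ALT - old
                        errors.append((i, role, slot, old, ALT - old))
                        erroneous.add(role)
        genotypes = {}
        pls: dict[str, tuple[int, int, int] | None] = {}
        for role in ROLES:
            if rng.random() < config.missing_rate:
                genotypes[role] = Genotype.unphased(MISSING, MISSING)
                pls[role] = None
                missing.append((i, role))
                continue
            a, b = observed[role]
            genotypes[role] = Genotype.unphased(a, b)
            depth = rng.poisson(config.mean_depth)
            if role in erroneous or role in hemi:
                margin = int(rng.exponential(8.0)) + 1
            elif rng.random() < 0.04:
                margin = int(rng.uniform(0, 18))
            else:
                margin = int(rng.gamma(4.0, max(depth, 1) * 0.375)) + 1
            far = margin + 30
            n_alt = a + b
            triplet = {0: (0, margin, far), 1: (margin, 0, far),
                       2: (far, margin, 0)}[n_alt]
            pls[role] = triplet
        sites.append(QuartetSite(
            chrom=st.chrom, pos=st.pos, ref="A", alt="G",
            genotypes=genotypes, pl=pls))

    # --- coverage --------------------------------------------------------------
    bw = config.coverage_bin_width
    high_regions: list[tuple[str, int, int]] = []
    for _ in range(config.n_high_depth_regions):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_weights))]
        length = config.chromosome_lengths[chrom]
        start = int(rng.integers(0, max(1, length - config.high_depth_length)))
        high_regions.append((chrom, start, start + config.high_depth_length))
    coverage: dict[str, CoverageTrack] = {}
    for role in ROLES:
        counts = {}
        for chrom, length in config.chromosome_lengths.items():
            n_bins = (length + bw - 1) // bw
            c = rng.poisson(config.mean_depth, size=n_bins).astype(float)
            for hchrom, hs, he in high_regions:
                if hchrom == chrom:
                    c[hs // bw: (he + bw - 1) // bw] *= 4.0
            for d in deletions:
                if d.sv.chrom == chrom and d.sv.genotypes.get(role) == (0, 1):
                    c[d.sv.start // bw: (d.sv.end + bw - 1) // bw] *= 0.5
            counts[chrom] = c
        coverage[role] = CoverageTrack(role, bw, counts)

    truth = SimTruth(config, site_truth, transmission, crossovers, errors,
                     missing, deletions, segments, high_regions)
    return SimResult(truth, sites, coverage)


# ---------------------------------------------------------------------------
# Phase fragments
# ---------------------------------------------------------------------------

def _sample_homolog_allele(st: SiteTruth, role: str, homolog: int) -> int:
    return st.ordered(role)[homolog]


def emit_fragments(truth: SimTruth, sample: str,
                   seed: int | None = None,
                   exhaustive: bool = False) -> list[PhaseFragment]:
    """Sequencing-fragment allele co-observations for one sample.

    Each fragment samples one homolog and reports its alleles at the
    heterozygous sites it covers (with optional per-observation error).
    ``exhaustive=True`` instead links every pair of adjacent heterozygous
    sites on homolog 0, giving complete physical connectivity per
    chromosome.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    het_sites: dict[str, list[SiteTruth]] = {}
    for st in truth.site_truth:
        o = st.ordered(sample)
        if o[0] != o[1]:
            het_sites.setdefault(st.chrom, []).append(st)
    fragments: list[PhaseFragment] = []
    fid = 0
    if exhaustive:
        for chrom, sts in het_sites.items():
            for a, b in zip(sts, sts[1:]):
                fragments.append(PhaseFragment(
                    fragment_id=f"{sample}_x{fid}", sample=sample,
                    observations=[((chrom, a.pos), a.ordered(sample)[0]),
                                  ((chrom, b.pos), b.ordered(sample)[0])]))
                fid += 1
        return fragments
    inserts = np.array(config.fragment_insert_sizes, dtype=float)
    mean_insert = float(inserts.mean())
    for chrom, length in config.chromosome_lengths.items():
        sts = het_sites.get(chrom, [])
        if not sts:
            continue
        positions = [st.pos for st in sts]
        n_frags = int(config.fragment_coverage * length / mean_insert)
        starts = rng.integers(1, length, size=n_frags)
        sizes = inserts[rng.integers(len(inserts), size=n_frags)]
        homologs = rng.integers(2, size=n_frags)
        for s, size, h in zip(starts, sizes, homologs):
            lo = bisect_right(positions, int(s) - 1)
            hi = bisect_right(positions, int(s + size))
            if hi - lo < 2:
                continue
            obs = []
            for st in sts[lo:hi]:
                allele = _sample_homolog_allele(st, sample, int(h))
                if rng.random() < config.fragment_error_rate:
                    allele = ALT - allele
                obs.append(((chrom, st.pos), allele))
            fragments.append(PhaseFragment(f"{sample}_f{fid}", sample, obs))
            fid += 1
    return fragments


# ---------------------------------------------------------------------------
# Surrogate population phasing
# ---------------------------------------------------------------------------

def emit_population_phasing(truth: SimTruth, switch_rate: float | None = None,
                            seed: int | None = None) -> tuple[dict, dict]:
    """Two trio-phased surrogate call sets (trio A: child1; trio B: child2).

    Phases are the truth with a Markov switch-error process applied
    independently per sample and per trio: at each heterozygous site the
    running orientation toggles with probability ``switch_rate``. Children
    are ordered Maternal|Paternal, parents hap0|hap1. Every site carries the
    true genotype, so the output can also impute MIE/SCE/uncalled positions.
    """
    config = truth.config
    rate = config.population_switch_rate if switch_rate is None else switch_rate
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    trios = {"a": ("father", "mother", "child1"),
             "b": ("father", "mother", "child2")}
    out: dict[str, dict] = {"a": {}, "b": {}}
    by_chrom: dict[str, list[SiteTruth]] = {}
    for st in truth.site_truth:
        by_chrom.setdefault(st.chrom, []).append(st)
    for trio, roles in trios.items():
        for role in roles:
            for chrom, sts in by_chrom.items():
                flip = False
                for st in sts:
                    o = st.ordered(role)
                    if o[0] != o[1]:
                        if rng.random() < rate:
                            flip = not flip
                    rec = out[trio].setdefault((chrom, st.pos), {})
                    rec[role] = {"ordered": o[::-1] if flip else o,
                                 "alleles": tuple(sorted(o))}
    return out["a"], out["b"]


# ---------------------------------------------------------------------------
# Per-sample haplotype-density tracks (for haplotype-block calling)
# ---------------------------------------------------------------------------

#: per-class densities (SNP/kb) on the three genotype tracks, mirroring the
#: haplotype structure of a phased genome: each block class is rich in one
#: (or several) of the hom 1|1 / het 0|1 / het 1|0 tracks.
TRACK_CLASS_SPECS: dict[str, tuple[float, dict[str, float]]] = {
    "0|1": (0.1206, {"0|1": 1.29, "1|0": 0.05, "1|1": 0.05}),
    "1|0": (0.1359, {"0|1": 0.05, "1|0": 1.28, "1|1": 0.05}),
    "1|1": (0.2000, {"0|1": 0.05, "1|0": 0.05, "1|1": 1.24}),
    "mixed": (0.1835, {"0|1": 0.72, "1|0": 0.72, "1|1": 0.71}),
    "SNP-poor": (0.3600, {"0|1": 0.12, "1|0": 0.12, "1|1": 0.12}),
}


def simulate_haplotype_tracks(chrom_lengths: dict[str, int],
                              seed: int = 0,
                              block_length_mean: float = 58_500.0,
                              class_specs: dict | None = None
                              ) -> tuple[dict, list[tuple[str, int, int, str]]]:
    """Per-sample genotype-track positions with known block classes.

    Returns ``(tracks, segments)`` where ``tracks[chrom][track]`` is a sorted
    position array for the three tracks ("1|1", "0|1", "1|0") and segments
    lists the generating ``(chrom, start, end, class)`` truth.
    """
    specs = class_specs or TRACK_CLASS_SPECS
    rng = np.random.default_rng(seed)
    names = sorted(specs)
    probs = np.array([specs[n][0] for n in names])
    probs = probs / probs.sum()
    tracks: dict[str, dict[str, list[int]]] = {}
    segments: list[tuple[str, int, int, str]] = []
    for chrom, length in chrom_lengths.items():
        per_track: dict[str, list[int]] = {"1|1": [], "0|1": [], "1|0": []}
        pos = 0
        while pos < length:
            seg_len = max(2000, int(rng.exponential(block_length_mean)))
            end = min(length, pos + seg_len)
            cls = names[int(rng.choice(len(names), p=probs))]
            segments.append((chrom, pos, end, cls))
            for track, dens in specs[cls][1].items():
                n = rng.poisson((end - pos) * dens / 1000.0)
                per_track[track].extend(
                    int(p) for p in rng.integers(pos + 1, end + 1, size=n))
            pos = end
        tracks[chrom] = {t: sorted(set(ps)) for t, ps in per_track.items()}
    return tracks, segments
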