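"""Reading and writing the formats the pipeline touches.

VCF handling goes through pysam. Only biallelic SNP/indel records enter the
analysis model; multi-allelic and symbolic-ALT records are counted and
logged, never silently dropped. The custom annotations are the AA FORMAT
field (parental allele of origin), the PT FORMAT field (phase tier:
transmission/physical/population) and the MIE/SCE INFO flags. Hemizygous
genotypes are serialized as haploid calls.

BED intervals are 0-based half-open; VCF positions 1-based. This module is
the only place the two conventions meet.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import pysam

from .merge import PhaseFragment
from .model import (DEL, MISSING, ROLES, Genotype, Pedigree, QuartetSite,
                    RegionSet, sites_sorted)
from .sv import SVCall

log = logging.getLogger(__name__)

_NUCS = frozenset("ACGTN")


@dataclass(slots=True)
class VcfReadResult:
    sites: list[QuartetSite]
    n_skipped_multiallelic: int = 0
    n_skipped_symbolic: int = 0

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def _clean_str(value) -> str | None:
    """Per-sample String values absent in a record read back as filler bytes."""
    if not value or value == "." or "\x07" in value:
        return None
    return value


def _genotype_from_record(sample) -> Genotype:
    gt = sample.get("GT", (None, None))
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return Genotype.unphased(MISSING, MISSING)
    if len(gt) == 1:  # haploid call: hemizygous genotype
        return Genotype.unphased(gt[0], DEL)
    a, b = (MISSING if x is None else int(x) for x in gt)
    if sample.phased:
        return Genotype.phased_pair(a, b)
    return Genotype.unphased(a, b)


def read_quartet_vcf(path: str, pedigree: Pedigree) -> VcfReadResult:
    """Load a 4-sample VCF into the quartet site model."""
    result = VcfReadResult([])
    with pysam.VariantFile(path) as vcf:
        has_error_flags = ("MIE" in vcf.header.info
                           and "SCE" in vcf.header.info)
        header_samples = list(vcf.header.samples)
        for sid in pedigree.sample_ids:
            if sid not in header_samples:
                raise ValueError(f"pedigree sample {sid!r} absent from VCF header")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                result.n_skipped_multiallelic += 1
                continue
            alt = alts[0]
            if alt.startswith("<") or not set(alt.upper()) <= _NUCS:
                result.n_skipped_symbolic += 1
                continue
            genotypes: dict[str, Genotype] = {}
            pls: dict[str, tuple[int, int, int] | None] = {}
            sources: dict[str, str] = {}
            origins: dict[str, str] = {}
            for role in ROLES:
                sample = rec.samples[pedigree.sample_of(role)]
                genotypes[role] = _genotype_from_record(sample)
                pl = sample.get("PL")
                if pl is None or any(x is None for x in pl):
                    pls[role] = None
                else:
                    pls[role] = tuple(int(x) for x in pl)
                pt = _clean_str(sample.get("PT"))
                if pt:
                    sources[role] = pt
                aa = _clean_str(sample.get("AA"))
                if aa:
                    origins[role] = aa
            error_class = None
            if has_error_flags:
                error_class = ("MIE" if rec.info.get("MIE")
                               else "SCE" if rec.info.get("SCE") else None)
            hemi = tuple(r for r in ROLES if DEL in genotypes[r].alleles)
            result.sites.append(QuartetSite(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                genotypes=genotypes, pl=pls,
                filter_status=tuple(rec.filter.keys()) or ("PASS",),
                phase_source=sources, parental_origin=origins,
                error_class=error_class, hemizygous=hemi))
    skipped = result.n_skipped_multiallelic + result.n_skipped_symbolic
    if skipped:
        log.info("skipped %d multi-allelic and %d symbolic records in %s",
                 result.n_skipped_multiallelic, result.n_skipped_symbolic, path)
    return result


def _build_header(sites: list[QuartetSite], pedigree: Pedigree) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    filters: set[str] = set()
    for s in sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
        filters.update(s.filter_status)
    for chrom, max_pos in contigs.items():
        header.contigs.add(chrom, length=max_pos + 1)
    for f in sorted(filters - {"PASS"}):
        header.filters.add(f, None, None, "recalibration tier")
    header.info.add("MIE", 0, "Flag", "Mendelian inheritance error")
    header.info.add("SCE", 0, "Flag", "State consistency error")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add("PT", 1, "String",
                       "Phase tier: transmission, physical or population")
    header.formats.add("AA", 1, "String", "Parental allele of origin")
    for sid in pedigree.sample_ids:
        header.add_sample(sid)
    return header


def write_phased_vcf(sites: list[QuartetSite], path: str,
                     pedigree: Pedigree) -> None:
    """Serialize sites to VCF; round-trips every downstream-relevant field."""
    if not sites_sorted(sites):
        raise ValueError("sites must be position-sorted within chromosomes")
    header = _build_header(sites, pedigree)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for s in sites:
            rec = vcf.new_record(contig=s.chrom, start=s.pos - 1,
                                 alleles=(s.ref, s.alt))
            for f in s.filter_status:
                rec.filter.add(f)
            if s.error_class == "MIE":
                rec.info["MIE"] = True
            elif s.error_class == "SCE":
                rec.info["SCE"] = True
            for role in ROLES:
                sample = rec.samples[pedigree.sample_of(role)]
                gt = s.gt(role)
                if DEL in (gt.a, gt.b):
                    kept = gt.a if gt.b == DEL else gt.b
                    sample["GT"] = (kept,)
                elif gt.is_missing():
                    sample["GT"] = (None, None)
                else:
                    sample["GT"] = (gt.a, gt.b)
                    sample.phased = gt.phased
                if s.pl.get(role) is not None:
                    sample["PL"] = s.pl[role]
                if role in s.phase_source:
                    sample["PT"] = s.phase_source[role]
                if role in s.parental_origin:
                    sample["AA"] = s.parental_origin[role]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_regions_bed(path: str, label: str = "") -> RegionSet:
    """Read BED3+ into a normalized RegionSet (0-based half-open)."""
    rs = RegionSet(label=label)
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{line_no}: end <= start")
            rs.add(chrom, start, end)
    return rs.normalize()


def write_regions_bed(rs: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in rs:
            name = f"\t{rs.label}" if rs.label else ""
            fh.write(f"{chrom}\t{start}\t{end}{name}\n")


def write_blocks_bed(blocks, crossovers, path: str) -> None:
    """Inheritance blocks and crossovers as named BED intervals."""
    rows = [(b.chrom, b.start, b.end, f"{b.parent}:{b.state}") for b in blocks]
    rows += [(c.chrom, c.start, c.end, f"{c.parent}:crossover")
             for c in crossovers if c.end > c.start]
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Tabular fragment and SV files
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["fragment_id", "sample", "chrom", "pos", "allele"]


def write_fragments_tsv(fragments: list[PhaseFragment], path: str) -> None:
    rows = [(f.fragment_id, f.sample, chrom, pos, allele)
            for f in fragments for (chrom, pos), allele in f.observations]
    pd.DataFrame(rows, columns=FRAGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str) -> list[PhaseFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fragment table misses columns: {sorted(missing)}")
    out: dict[tuple[str, str], PhaseFragment] = {}
    for row in df.itertuples(index=False):
        key = (row.fragment_id, row.sample)
        frag = out.setdefault(key, PhaseFragment(row.fragment_id, row.sample, []))
        frag.observations.append(((row.chrom, int(row.pos)), int(row.allele)))
    return list(out.values())


SV_COLUMNS = ["chrom", "start", "end", "svtype", "caller",
              "father", "mother", "child1", "child2"]
_GT_STR = {(0, 0): "0/0", (0, 1): "0/1", (1, 1): "1/1", None: "."}
_STR_GT: dict[str, tuple[int, int] | None] = {v: k for k, v in _GT_STR.items()}


def write_sv_tsv(calls: list[SVCall], path: str) -> None:
    rows = []
    for c in calls:
        rows.append((c.chrom, c.start, c.end, c.svtype, c.caller,
                     *(_GT_STR[c.genotypes.get(r)] for r in ROLES)))
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: str) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SV table misses columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        gts = {role: _STR_GT[getattr(row, role)] for role in ROLES}
        calls.append(SVCall(row.chrom, int(row.start), int(row.end),
                            row.svtype, row.caller, gts))
    return calls


def read_pedigree_file(path: str) -> Pedigree:
    """Read a two-column (role, sample) or one-line four-sample pedigree."""
    with open(path) as fh:
        tokens = [t for line in fh
                  for t in line.split() if not line.startswith("#")]
    if len(tokens) == 4:
        return Pedigree(*tokens)
    if len(tokens) == 8:
        mapping = dict(zip(tokens[0::2], tokens[1::2]))
        return Pedigree(mapping["father"], mapping["mother"],
                        mapping["child1"], mapping["child2"])
    raise ValueError(f"cannot parse pedigree file {path!r}")


def read_phased_calls(path: str, sample_to_role: dict[str, str]) -> dict:
    """Read externally phased calls (e.g. a population-phased trio VCF).

    Returns ``{(chrom, pos): {role: {"ordered": (a, b), "alleles": (a, b)}}}``
    for the requested samples, keeping only biallelic records.
    """
    out: dict = {}
    with pysam.VariantFile(path) as vcf:
        for sid in sample_to_role:
            if sid not in list(vcf.header.samples):
                raise ValueError(f"sample {sid!r} absent from {path}")
        for rec in vcf:
            if not rec.alts or len(rec.alts) != 1:
                continue
            entry: dict = {}
            for sid, role in sample_to_role.items():
                gt = rec.samples[sid].get("GT", (None, None))
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    continue
                ordered = (int(gt[0]), int(gt[1]))
                entry[role] = {"ordered": ordered,
                               "alleles": tuple(sorted(ordered))}
            if entry:
                out[(rec.chrom, rec.pos)] = entry
    return out


# ---------------------------------------------------------------------------
# Variant-quality summary
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ti_tv_ratio(sites: list[QuartetSite]) -> float:
    """Transition/transversion ratio over SNP sites; inf if no transversions."""
    ti = tv = 0
    for s in sites:
        if not s.is_snp():
            continue
        if (s.ref.upper(), s.alt.upper()) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return float("inf")
    return ti / tv
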