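"""Format round-trips: VCF, BED, fragment and SV tables."""
import copy

import numpy as np
import pytest

from helpers_quartet import make_site
from quartet_phase.model import (ALT, DEL, MISSING, REF, ROLES, Genotype,
                                 Pedigree, RegionSet)
from quartet_phase.vcf_io import (read_fragments_tsv, read_pedigree_file,
                                  read_quartet_vcf, read_regions_bed,
                                  read_sv_tsv, ti_tv_ratio, write_fragments_tsv,
                                  write_phased_vcf, write_regions_bed,
                                  write_sv_tsv)

PED = Pedigree("FNY_2_2", "FNY_2_5", "FNY_3_2", "FNY_3_3")


def _write_vcf_text(path, body, samples=PED.sample_ids):
    header = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=1000000>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="PL">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n")
    path.write_text(header + body)


class TestReadVcf:
    def test_direct_mapping(self, tmp_path):
        p = tmp_path / "q.vcf"
        _write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t"
                           "0/1\t0/0\t0/1\t0/0\n")
        result = read_quartet_vcf(str(p), PED)
        assert len(result) == 1
        site = result.sites[0]
        assert site.gt("father").alleles == (REF, ALT)
        assert site.gt("mother").alleles == (REF, REF)
        assert not any(site.gt(r).phased for r in ROLES)

    def test_missing_genotype(self, tmp_path):
        p = tmp_path / "q.vcf"
        _write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t"
                           "0/1\t0/0\t0/1\t./.\n")
        site = read_quartet_vcf(str(p), PED).sites[0]
        assert site.gt("child2").alleles == (MISSING, MISSING)

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        p = tmp_path / "q.vcf"
        _write_vcf_text(p, "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t"
                           "0/1\t0/0\t0/2\t0/0\n"
                           "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t"
                           "0/1\t0/0\t0/1\t0/0\n")
        result = read_quartet_vcf(str(p), PED)
        assert len(result) == 1
        assert result.n_skipped_multiallelic == 1

    def test_unknown_sample_rejected(self, tmp_path):
        p = tmp_path / "q.vcf"
        _write_vcf_text(p, "", samples=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            read_quartet_vcf(str(p), PED)


class TestRoundTrip:
    def test_simulated_sites_round_trip(self, tmp_path, noisy_sim):
        """write(read(x)) == x for all downstream-relevant fields."""
        from quartet_phase.transmission import phase_quartet
        sites = copy.deepcopy(noisy_sim.sites[:100])
        phase_quartet(sites)
        sites[0].error_class = "MIE"
        sites[1].error_class = "SCE"
        from quartet_phase.merge import annotate_parental_origin
        annotate_parental_origin(sites)
        path = str(tmp_path / "out.vcf")
        write_phased_vcf(sites, path, PED)
        back = read_quartet_vcf(path, PED).sites
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert a.error_class == b.error_class
            for r in ROLES:
                assert a.gt(r).alleles == b.gt(r).alleles
                assert a.gt(r).phased == b.gt(r).phased
                if a.gt(r).phased:
                    assert a.gt(r).ordered == b.gt(r).ordered
                assert a.pl[r] == b.pl[r]
                assert a.phase_source.get(r) == b.phase_source.get(r)
                assert a.parental_origin.get(r) == b.parental_origin.get(r)

    def test_hemizygous_round_trip(self, tmp_path):
        site = make_site(father=(REF, ALT), mother=(REF, REF),
                         child1=(REF, REF), child2=(REF, REF), pos=10)
        site.genotypes["father"] = Genotype.unphased(ALT, DEL)
        site.hemizygous = ("father",)
        path = str(tmp_path / "h.vcf")
        write_phased_vcf([site], path, PED)
        back = read_quartet_vcf(path, PED).sites[0]
        assert DEL in back.gt("father").alleles
        assert back.hemizygous == ("father",)

    def test_unsorted_input_rejected(self, tmp_path):
        sites = [make_site(father=(REF, ALT), mother=(REF, REF),
                           child1=(REF, REF), child2=(REF, REF), pos=p)
                 for p in (20, 10)]
        with pytest.raises(ValueError):
            write_phased_vcf(sites, str(tmp_path / "x.vcf"), PED)


class TestBed:
    def test_basic_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        rs = read_regions_bed(str(p))
        assert rs.intervals("chr1") == [(10, 20)]
        assert rs.contains("chr1", 10) and not rs.contains("chr1", 20)

    def test_overlapping_intervals_normalized(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        assert read_regions_bed(str(p)).intervals("chr1") == [(10, 30)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_regions_bed(str(p))) == 0

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t20\t10\n")
        with pytest.raises(ValueError):
            read_regions_bed(str(p))

    def test_round_trip(self, tmp_path):
        rs = RegionSet({"chr1": [(0, 5), (10, 20)], "chr2": [(7, 9)]})
        path = str(tmp_path / "r.bed")
        write_regions_bed(rs, path)
        assert read_regions_bed(path) == rs


class TestTables:
    def test_fragment_round_trip(self, tmp_path, clean_sim):
        from quartet_phase.simulate import emit_fragments
        frags = emit_fragments(clean_sim.truth, "child1",
                               exhaustive=True)[:50]
        path = str(tmp_path / "f.tsv")
        write_fragments_tsv(frags, path)
        back = read_fragments_tsv(path)
        assert {f.fragment_id for f in back} == {f.fragment_id for f in frags}
        by_id = {f.fragment_id: f for f in back}
        for f in frags:
            assert by_id[f.fragment_id].observations == f.observations

    def test_sv_round_trip(self, tmp_path):
        from quartet_phase.sv import SVCall
        calls = [SVCall("chr1", 100, 900, "DEL", "pindel",
                        {"father": (0, 1), "mother": (0, 0),
                         "child1": (0, 1), "child2": None}),
                 SVCall("chr2", 5, 4000, "DUP", "cnvnator",
                        {r: (0, 0) for r in ROLES})]
        path = str(tmp_path / "sv.tsv")
        write_sv_tsv(calls, path)
        assert read_sv_tsv(path) == calls

    def test_pedigree_file_formats(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("father F\nmother M\nchild1 C1\nchild2 C2\n")
        assert read_pedigree_file(str(p)) == Pedigree("F", "M", "C1", "C2")
        p.write_text("F M C1 C2\n")
        assert read_pedigree_file(str(p)) == Pedigree("F", "M", "C1", "C2")


class TestTiTv:
    def _snp(self, ref, alt, pos):
        s = make_site(father=(REF, ALT), mother=(REF, REF),
                      child1=(REF, REF), child2=(REF, REF), pos=pos)
        s.ref, s.alt = ref, alt
        return s

    def test_by_definition(self):
        sites = [self._snp("A", "G", 1), self._snp("C", "T", 2),
                 self._snp("A", "C", 3)]
        assert ti_tv_ratio(sites) == pytest.approx(2.0)

    def test_all_transversions(self):
        sites = [self._snp("A", "C", 1), self._snp("G", "T", 2)]
        assert ti_tv_ratio(sites) == 0.0

    def test_no_transversions_is_infinite(self):
        assert ti_tv_ratio([self._snp("A", "G", 1)]) == float("inf")

    def test_binomial_sampling_recovers_two_to_one(self):
        rng = np.random.default_rng(12)
        sites = []
        for i in range(3000):
            if rng.random() < 2 / 3:
                sites.append(self._snp("A", "G", i + 1))
            else:
                sites.append(self._snp("A", "T", i + 1))
        assert ti_tv_ratio(sites) == pytest.approx(2.0, abs=0.15)
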