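"""MIE/SCE classification, estimators and the detectability enumeration."""
from itertools import product

import pytest

from helpers_quartet import (GT_COMBOS, STATES, make_site, oracle_marker_sce,
                             oracle_quartet_mie)
from quartet_phase.blocks import ConstantBlockMap
from quartet_phase.errors import (ErrorReport, classify_corrupted,
                                  classify_mie, classify_sce,
                                  concordance_report, enumerate_detectability,
                                  estimate_true_variants,
                                  quartet_configurations, regional_error_rate,
                                  true_haplotypes)
from quartet_phase.model import ALT, REF, RegionSet


class TestClassifyMie:
    def test_exhaustive_grid_matches_bruteforce(self):
        for m, f, c1, c2 in product(GT_COMBOS, repeat=4):
            site = make_site(father=f, mother=m, child1=c1, child2=c2)
            assert classify_mie(site) == oracle_quartet_mie(m, f, c1, c2), \
                (m, f, c1, c2)

    def test_hom_ref_parents_het_child(self):
        site = make_site(father=(REF, REF), mother=(REF, REF),
                         child1=(REF, ALT), child2=(REF, REF))
        assert classify_mie(site) is True

    def test_missing_genotype_not_classified(self):
        from quartet_phase.model import MISSING
        site = make_site(father=(REF, REF), mother=(REF, REF),
                         child1=(REF, ALT), child2=(MISSING, MISSING))
        assert classify_mie(site) is None


class TestClassifySce:
    @pytest.mark.parametrize("s_m,s_p", STATES)
    def test_exhaustive_grid_matches_bruteforce(self, s_m, s_p):
        blocks = ConstantBlockMap(s_m, s_p)
        for m, f, c1, c2 in product(GT_COMBOS, repeat=4):
            site = make_site(father=f, mother=m, child1=c1, child2=c2)
            got = classify_sce(site, blocks)
            want = oracle_marker_sce(m, f, c1, c2, s_m, s_p)
            assert bool(got) == bool(want), (m, f, c1, c2, s_m, s_p)

    def test_maternal_snp_absent_in_inheriting_child(self):
        """The canonical SCE: mother hom-ALT transmits the SNP to both
        children under "different" state impossibility."""
        site = make_site(father=(REF, REF), mother=(ALT, ALT),
                         child1=(REF, ALT), child2=(REF, ALT))
        # mother hom: her marker is undefined; make her het instead
        site = make_site(father=(REF, REF), mother=(REF, ALT),
                         child1=(REF, ALT), child2=(REF, ALT))
        # both children carry the maternal ALT: marker "same"
        assert classify_sce(site, ConstantBlockMap("different", "different"))
        assert not classify_sce(site, ConstantBlockMap("same", "same"))

    def test_junction_not_classified(self):
        from quartet_phase.blocks import BlockMap
        site = make_site(father=(REF, REF), mother=(REF, ALT),
                         child1=(REF, ALT), child2=(REF, ALT))
        assert classify_sce(site, BlockMap([])) is None

    def test_mie_and_sce_mutually_exclusive(self):
        blocks = ConstantBlockMap("same", "different")
        for m, f, c1, c2 in product(GT_COMBOS, repeat=4):
            site = make_site(father=f, mother=m, child1=c1, child2=c2)
            if classify_mie(site):
                assert classify_sce(site, blocks) is None


class TestErrorReport:
    def test_published_snp_chain(self):
        base = ErrorReport(5_163_231, 153_552, 227_866)
        assert base.n_gde == 381_418
        assert base.gde_corrected == 4_781_813
        assert base.fp_pct == pytest.approx(2.66, abs=0.005)
        assert base.true_variant_estimate == 4_654_674
        rdf = ErrorReport(4_958_825, 139_757, 152_586)
        assert rdf.gde_corrected == 4_666_482
        assert rdf.fn_pct(base) == pytest.approx(2.47, abs=0.005)

    def test_zero_errors(self):
        rep = ErrorReport(1000, 0, 0)
        assert rep.fp_pct == 0.0
        assert rep.true_variant_estimate == 1000

    def test_estimate_true_variants(self):
        assert estimate_true_variants(5_163_231, 381_418) == 4_654_674
        assert estimate_true_variants(100, 0) == 100
        with pytest.raises(ValueError):
            estimate_true_variants(10, 1, detectable_fraction=0.0)


class TestEnumeration:
    def test_every_corruption_classified_exactly_once(self):
        """MIE / SCE / undetected partition each corrupted configuration."""
        for config in quartet_configurations():
            truth = true_haplotypes(config)
            sm, sp = config[2], config[3]
            for role in truth:
                for slot in (0, 1):
                    obs = {r: tuple(sorted(h)) for r, h in truth.items()}
                    flipped = list(truth[role])
                    flipped[slot] = ALT - flipped[slot]
                    obs[role] = tuple(sorted(flipped))
                    assert classify_corrupted(obs, sm, sp) in ("MIE", "SCE", None)

    def test_all_ref_config_excluded(self):
        assert len(quartet_configurations()) == 60
        assert all(any(a == ALT for h in true_haplotypes(c).values() for a in h)
                   for c in quartet_configurations())

    def test_per_config_fractions_bounded(self):
        table = enumerate_detectability()
        for fracs in table.per_config.values():
            for v in fracs.values():
                assert 0.0 <= v <= 1.0
        assert 0.0 < table.detect_parents < table.detect_children <= 1.0

    def test_forced_child_miscall_is_mie(self):
        # everyone REF except one child miscalled het
        obs = {"mother": (REF, REF), "father": (REF, REF),
               "child1": (REF, ALT), "child2": (REF, REF)}
        assert classify_corrupted(obs, "same", "same") == "MIE"

    def test_non_sporadic_mode_runs(self):
        table = enumerate_detectability("non_sporadic")
        assert 0.0 < table.detect_children <= 1.0
        assert 0.0 < table.detect_parents <= 1.0


class TestRates:
    def test_regional_rate_arithmetic(self):
        sites = [make_site(father=(REF, REF), mother=(REF, REF),
                           child1=(REF, ALT), child2=(REF, REF), pos=p)
                 for p in range(1, 11)]
        for s in sites:
            s.error_class = "MIE"
        regions = RegionSet({"chr1": [(0, 10_000_000)]})
        rate = regional_error_rate(sites, regions, n_genomes=4)
        assert rate == pytest.approx(2.5e-7)
        with pytest.raises(ValueError):
            regional_error_rate(sites, RegionSet(), n_genomes=4)

    def test_concordance(self):
        a = {("chr1", p): (REF, ALT) for p in range(100)}
        assert concordance_report(a, dict(a))["pct_concordant"] == 100.0
        b = dict(a)
        b[("chr1", 0)] = (ALT, ALT)
        out = concordance_report(a, b)
        assert out["n_discordant"] == 1
        with pytest.raises(ValueError):
            concordance_report(a, {("chr9", 1): (REF, REF)})

    def test_published_platform_concordance(self):
        out = {"n_both": 494_844, "n_concordant": 493_014}
        pct = 100.0 * out["n_concordant"] / out["n_both"]
        assert pct == pytest.approx(99.63, abs=0.005)
        # same computation through the API on a small synthetic scale
        a = {("chr1", i): (REF, ALT) for i in range(10_000)}
        b = {k: ((ALT, ALT) if i < 37 else v)
             for i, (k, v) in enumerate(a.items())}
        rep = concordance_report(a, b)
        assert rep["pct_discordant"] == pytest.approx(0.37)
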