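"""Phase-set construction and multi-source phase merging."""
import numpy as np
import pytest

from helpers_quartet import make_site, oracle_nx
from quartet_phase.merge import (PhaseFragment, build_phase_sets,
                                 classify_double_het, integrate_physical,
                                 integrate_population, phase_set_stats,
                                 phasing_rate_report)
from quartet_phase.model import ALT, CHILDREN, REF, ROLES
from quartet_phase.transmission import phase_quartet, resolve_triple_het


def frag(fid, sample, obs):
    return PhaseFragment(fid, sample, [(("chr1", p), a) for p, a in obs])


class TestBuildPhaseSets:
    def test_transitive_linkage(self):
        frags = [frag("f1", "child1", [(10, ALT), (20, REF)]),
                 frag("f2", "child1", [(20, REF), (30, ALT)])]
        hets = {("chr1", p) for p in (10, 20, 30)}
        sets = build_phase_sets(frags, hets)
        assert len(sets) == 1
        ps = sets[0]
        assert ps.n_sites == 3
        # one homolog carries ALT, REF, ALT in order
        bits = [ps.orientation[("chr1", p)] for p in (10, 20, 30)]
        assert bits in ([ALT, REF, ALT], [REF, ALT, REF])

    def test_tied_votes_drop_the_edge(self):
        frags = [frag("f1", "child1", [(10, ALT), (20, REF)]),
                 frag("f2", "child1", [(10, ALT), (20, ALT)])]
        hets = {("chr1", 10), ("chr1", 20)}
        sets = build_phase_sets(frags, hets)
        assert sorted(ps.n_sites for ps in sets) == [1, 1]

    def test_majority_vote_wins(self):
        frags = [frag(f"f{i}", "child1", [(10, ALT), (20, REF)])
                 for i in range(3)]
        frags.append(frag("f9", "child1", [(10, ALT), (20, ALT)]))
        sets = build_phase_sets(frags, {("chr1", 10), ("chr1", 20)})
        assert len(sets) == 1
        ps = sets[0]
        assert ps.orientation[("chr1", 10)] != ps.orientation[("chr1", 20)]

    def test_error_free_fragments_reconstruct_truth(self, clean_sim):
        from quartet_phase.simulate import emit_fragments
        truth = clean_sim.truth
        for sample in ("child1", "mother"):
            frags = emit_fragments(truth, sample, exhaustive=True)
            het_truth = {("chr1", st.pos): st.ordered(sample)
                         for st in truth.site_truth
                         if st.ordered(sample)[0] != st.ordered(sample)[1]}
            sets = build_phase_sets(frags, set(het_truth))
            assert len(sets) == 1
            ps = sets[0]
            flips = {ps.orientation[k] == het_truth[k][0] for k in het_truth}
            assert len(flips) == 1  # globally consistent with one homolog


class TestIntegratePhysical:
    def test_quad_het_inherits_anchor_orientation(self):
        anchor = make_site(father=(REF, REF), mother=(REF, ALT),
                           child1=(REF, ALT), child2=(REF, REF), pos=10)
        quad = make_site(father=(REF, ALT), mother=(REF, ALT),
                         child1=(REF, ALT), child2=(REF, ALT), pos=20)
        sites = [anchor, quad]
        phase_quartet(sites)
        assert anchor.gt("child1").ordered == (ALT, REF)
        frags = [frag("f1", "child1", [(10, ALT), (20, REF)])]
        sets = build_phase_sets(frags, {("chr1", 10), ("chr1", 20)})
        r = integrate_physical(sites, sets)
        assert r.n_phased == 1 and r.n_divergent == 0
        # fragment homolog carrying ALT@10 is maternal, so REF@20 is maternal
        assert quad.gt("child1").ordered == (REF, ALT)
        assert quad.source("child1") == "physical"

    def test_set_without_anchor_stays_unphased(self):
        quad1 = make_site(father=(REF, ALT), mother=(REF, ALT),
                          child1=(REF, ALT), child2=(REF, ALT), pos=10)
        quad2 = make_site(father=(REF, ALT), mother=(REF, ALT),
                          child1=(REF, ALT), child2=(REF, ALT), pos=20)
        sites = [quad1, quad2]
        phase_quartet(sites)
        sets = build_phase_sets([frag("f1", "child1", [(10, ALT), (20, REF)])],
                                {("chr1", 10), ("chr1", 20)})
        r = integrate_physical(sites, sets)
        assert r.n_phased == 0
        assert not quad1.gt("child1").phased

    def test_transmission_never_overridden(self, clean_sim):
        """phase_source precedence: a later tier never flips transmission."""
        import copy
        from quartet_phase.simulate import emit_fragments
        sites = copy.deepcopy(clean_sim.sites[:2000])
        phase_quartet(sites)
        before = {(s.key(), r): s.gt(r).ordered
                  for s in sites for r in ROLES
                  if s.source(r) == "transmission"}
        frags = emit_fragments(clean_sim.truth, "child1", exhaustive=True)
        hets = {s.key() for s in sites if s.gt("child1").is_het()}
        integrate_physical(sites, build_phase_sets(frags, hets))
        for s in sites:
            for r in ROLES:
                if (s.key(), r) in before:
                    assert s.gt(r).ordered == before[(s.key(), r)]


class TestIntegratePopulation:
    def _quad(self, pos):
        return make_site(father=(REF, ALT), mother=(REF, ALT),
                         child1=(REF, ALT), child2=(REF, ALT), pos=pos)

    def test_agreeing_trios_phase_quad_het(self):
        site = self._quad(10)
        phase_quartet([site])
        rec = {"father": {"ordered": (REF, ALT), "alleles": (REF, ALT)},
               "mother": {"ordered": (ALT, REF), "alleles": (REF, ALT)}}
        trio_a = {("chr1", 10): {**rec, "child1": {"ordered": (ALT, REF),
                                                   "alleles": (REF, ALT)}}}
        trio_b = {("chr1", 10): {**rec, "child2": {"ordered": (REF, ALT),
                                                   "alleles": (REF, ALT)}}}
        r = integrate_population([site], trio_a, trio_b)
        assert r.n_inconsistent == 0
        assert site.gt("child1").ordered == (ALT, REF)
        assert site.source("child1") == "population"

    def test_disagreeing_trios_are_dropped(self):
        site = self._quad(10)
        phase_quartet([site])
        trio_a = {("chr1", 10): {"father": {"ordered": (REF, ALT),
                                            "alleles": (REF, ALT)}}}
        trio_b = {("chr1", 10): {"father": {"ordered": (ALT, REF),
                                            "alleles": (REF, ALT)}}}
        r = integrate_population([site], trio_a, trio_b)
        assert r.n_inconsistent == 1
        assert not site.gt("child1").phased

    def test_mie_position_imputed_with_provenance(self):
        site = make_site(father=(REF, REF), mother=(REF, REF),
                         child1=(REF, ALT), child2=(REF, REF), pos=10)
        site.error_class = "MIE"
        trio_a = {("chr1", 10): {"child1": {"ordered": (REF, REF),
                                            "alleles": (REF, REF)}}}
        r = integrate_population([site], trio_a, {})
        assert r.n_imputed == 1
        assert site.gt("child1").alleles == (REF, REF)
        assert site.error_class == "MIE"          # provenance retained
        assert "imputed" in site.notes

    def test_switch_free_surrogate_is_fully_consistent(self, clean_sim):
        import copy
        from quartet_phase.simulate import emit_population_phasing
        trio_a, trio_b = emit_population_phasing(clean_sim.truth,
                                                 switch_rate=0.0)
        sites = copy.deepcopy(clean_sim.sites)
        phase_quartet(sites)
        r = integrate_population(sites, trio_a, trio_b)
        assert r.n_inconsistent == 0
        # every quad-het child genotype is now phased from the population set
        for s, st in zip(sites, clean_sim.truth.site_truth):
            if st.is_quad_het():
                for c in CHILDREN:
                    assert s.gt(c).ordered == st.ordered(c)

    def test_switch_errors_create_intertrio_inconsistencies(self, clean_sim):
        import copy
        from quartet_phase.simulate import emit_population_phasing
        trio_a, trio_b = emit_population_phasing(clean_sim.truth,
                                                 switch_rate=0.02, seed=9)
        sites = copy.deepcopy(clean_sim.sites)
        phase_quartet(sites)
        r = integrate_population(sites, trio_a, trio_b)
        assert r.n_inconsistent > 0


class TestPhaseSetStats:
    def test_single_and_two_span_examples(self):
        class S:  # minimal span carrier
            def __init__(self, span):
                self.span = span
        assert phase_set_stats([S(1000)]) == {"N10": 1000, "N50": 1000}
        assert phase_set_stats([S(900), S(100)]) == {"N10": 900, "N50": 900}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cumulative_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spans = [int(x) for x in rng.integers(100, 10_000, size=40)]
        class S:
            def __init__(self, span):
                self.span = span
        stats = phase_set_stats([S(s) for s in spans])
        assert stats["N10"] == oracle_nx(spans, 10)
        assert stats["N50"] == oracle_nx(spans, 50)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phase_set_stats([])


class TestDoubleHet:
    def _sites(self, orderings):
        sites = []
        for i, (a, b) in enumerate(orderings):
            s = make_site(father=(REF, ALT), mother=(REF, ALT),
                          child1=tuple(sorted((a, b))), child2=(REF, REF),
                          pos=100 + i)
            s.genotypes["child1"] = s.gt("child1").with_order(a, b)
            s.phase_source["child1"] = "transmission"
            sites.append(s)
        return sites

    def test_cis_trans_and_undetermined(self):
        genes = [("chr1", 0, 1000, "G1")]
        assert classify_double_het(
            genes, self._sites([(ALT, REF), (ALT, REF)]), "child1") == \
            {"G1": "cis"}
        assert classify_double_het(
            genes, self._sites([(ALT, REF), (REF, ALT)]), "child1") == \
            {"G1": "trans"}
        sites = self._sites([(ALT, REF), (ALT, REF)])
        sites[1].genotypes["child1"].phased = False
        assert classify_double_het(genes, sites, "child1") == \
            {"G1": "undetermined"}

    def test_single_het_gene_not_reported(self):
        genes = [("chr1", 0, 1000, "G1")]
        assert classify_double_het(genes, self._sites([(ALT, REF)]),
                                   "child1") == {}


class TestPhasingRateReport:
    def test_all_phased_is_100_pct(self):
        sites = [make_site(father=(REF, ALT), mother=(REF, REF),
                           child1=(REF, ALT), child2=(REF, REF), pos=p)
                 for p in (10, 20)]
        phase_quartet(sites)
        report = phasing_rate_report(sites)
        assert report.loc["quartet", "phased_pct"] == 100.0
        assert report.loc["child1", "het_phased_pct"] == 100.0

    def test_unphased_set_is_exactly_quad_het(self, clean_sim):
        import copy
        sites = copy.deepcopy(clean_sim.sites)
        phase_quartet(sites)
        resolve_triple_het(sites, clean_sim.truth.block_map())
        report = phasing_rate_report(sites)
        nq = sum(1 for st in clean_sim.truth.site_truth if st.is_quad_het())
        assert report.loc["quartet", "unphased"] == nq
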