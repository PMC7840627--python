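import itertools

import numpy as np
import pytest

from comphet.io_formats import VariantRecord, HOM_REF, HET, HOM_ALT, MISSING
from comphet.pedigree import Individual, Pedigree
from comphet.variant_filter import (ControlCohort, classify_inheritance,
                                    deduce_ancestor_carrier,
                                    filter_private, filter_protein_changing,
                                    phase_by_trio, prioritize, run_funnel,
                                    segregation_census)

TRIO = ("child", "sire", "dam")


def _var(pattern, gene="g", chrom="1", pos=100, ref="A", alt="G"):
    child, sire, dam = pattern
    return VariantRecord(chrom, pos, ref, alt, gene_id=gene,
                         genotypes={"child": child, "sire": sire, "dam": dam})


class TestEffectFilter:
    def test_synonymous_removed_missense_kept(self):
        vs = [VariantRecord("1", 1, "A", "G", effect_class="synonymous"),
              VariantRecord("1", 2, "A", "G", effect_class="missense")]
        out = filter_protein_changing(vs)
        assert [v.pos for v in out] == [2]

    def test_mixed_fixture_count_matches_hand_enumeration(self):
        effects = ["missense", "synonymous", "nonsense", "non_coding",
                   "frameshift", "splice_acceptor", "splice_donor",
                   "splice_region", "start_lost", "stop_lost",
                   "inframe_indel", "synonymous", "non_coding", "missense",
                   "other_protein_changing", "nonsense", "synonymous",
                   "missense", "non_coding", "splice_acceptor"]
        keep = {"missense", "nonsense", "frameshift", "splice_acceptor",
                "splice_donor", "start_lost", "stop_lost", "inframe_indel",
                "other_protein_changing"}
        vs = [VariantRecord("1", i + 1, "A", "G", effect_class=e)
              for i, e in enumerate(effects)]
        out = filter_protein_changing(vs)
        assert len(out) == sum(e in keep for e in effects)
        assert [v.pos for v in out] == [v.pos for v in vs
                                        if v.effect_class in keep]

    def test_unannotated_record_is_flagged(self):
        with pytest.raises(ValueError, match="unannotated"):
            filter_protein_changing([VariantRecord("1", 5, "A", "G")])


class TestPrivacyFilter:
    def test_control_carrier_removes_variant(self):
        v = VariantRecord("1", 10, "A", "G", genotypes={"c1": HET, "c2": HET})
        cohort = ControlCohort({v.key: 1}, n_samples=60)
        assert filter_private([v], ["c1", "c2"], cohort) == []
        assert filter_private([v], ["c1", "c2"], cohort,
                              max_control_carriers=1) == [v]

    def test_empty_cohort_is_identity_on_case_carried(self):
        carried = VariantRecord("1", 1, "A", "G",
                                genotypes={"c1": HET, "c2": HOM_ALT})
        not_carried = VariantRecord("1", 2, "A", "G",
                                    genotypes={"c1": HET, "c2": HOM_REF})
        out = filter_private([carried, not_carried], ["c1", "c2"],
                             ControlCohort({}, n_samples=0))
        assert out == [carried]

    def test_unobserved_in_controls_treated_as_zero(self):
        v = VariantRecord("1", 10, "A", "G", genotypes={"c1": HET})
        n, observed = ControlCohort({}, 60).carrier_count(v)
        assert (n, observed) == (0, False)


def _phase_oracle(c, s, d):
    """Independent enumeration of the trio-phasing rule."""
    if c != HET:
        return "not_applicable"
    if s == MISSING or d == MISSING:
        return "ambiguous"
    sire_can = s in (HET, HOM_ALT)
    dam_can = d in (HET, HOM_ALT)
    if sire_can and dam_can:
        return "ambiguous"
    if sire_can:
        return "paternal"
    if dam_can:
        return "maternal"
    return "mendelian_error"


class TestTrioPhasing:
    def test_all_27_genotype_configurations_match_oracle(self):
        for c, s, d in itertools.product((0, 1, 2), repeat=3):
            v = _var((c, s, d))
            assert phase_by_trio(v, TRIO) == _phase_oracle(c, s, d), (c, s, d)

    def test_study_patterns(self):
        assert phase_by_trio(_var((HET, HET, HOM_REF)), TRIO) == "paternal"
        assert phase_by_trio(_var((HET, HOM_REF, HET)), TRIO) == "maternal"
        assert phase_by_trio(_var((HET, HET, HET)), TRIO) == "ambiguous"


def _two_trio_family():
    samples = ["s", "d1", "d2", "c1", "c2"]
    trios = [("c1", "s", "d1"), ("c2", "s", "d2")]
    return samples, trios, ["c1", "c2"]


def _fam_var(pos, gene, gts, effect="missense"):
    samples = ["s", "d1", "d2", "c1", "c2"]
    return VariantRecord("1", pos, "A", "G", gene_id=gene, effect_class=effect,
                         genotypes=dict(zip(samples, gts)))


class TestClassifyInheritance:
    def test_recessive_pattern(self):
        _, trios, cases = _two_trio_family()
        v = _fam_var(10, "gR", [HET, HET, HET, HOM_ALT, HOM_ALT])
        calls = classify_inheritance([v], trios, cases)
        assert calls[0].mode == "recessive_hom"

    def test_compound_het_pair_with_opposite_origins(self):
        _, trios, cases = _two_trio_family()
        va = _fam_var(10, "gC", [HOM_REF, HET, HET, HET, HET])  # maternal
        vb = _fam_var(20, "gC", [HET, HOM_REF, HOM_REF, HET, HET])  # paternal
        calls = classify_inheritance([va, vb], trios, cases)
        comp = [c for c in calls if c.mode == "compound_het"]
        assert len(comp) == 1
        assert comp[0].gene_id == "gC"
        assert comp[0].phase_evidence["c1"] == ("maternal", "paternal")

    def test_cis_pair_rejected(self):
        _, trios, cases = _two_trio_family()
        va = _fam_var(10, "gC", [HET, HOM_REF, HOM_REF, HET, HET])
        vb = _fam_var(20, "gC", [HET, HOM_REF, HOM_REF, HET, HET])
        calls = classify_inheritance([va, vb], trios, cases)
        assert all(c.mode != "compound_het" for c in calls)

    def test_variant_absent_from_parents_is_mendelian_inconsistent(self):
        _, trios, cases = _two_trio_family()
        v = _fam_var(10, "gX", [HOM_REF, HOM_REF, HOM_REF, HET, HET])
        calls = classify_inheritance([v], trios, cases)
        assert calls[0].mode == "incompatible"
        assert calls[0].mendelian_inconsistency

    def test_requires_a_trio(self):
        with pytest.raises(ValueError):
            classify_inheritance([], [], ["c1"])


class TestSegregationCensus:
    def test_counts_sum_to_sample_count(self, fig2a):
        out = segregation_census(fig2a["var_a"], fig2a["var_b"],
                                 fig2a["samples"])
        assert sum(out["counts"].values()) == len(fig2a["samples"]) == 71

    def test_single_wildtype_animal(self):
        va = VariantRecord("1", 1, "A", "G", genotypes={"x": HOM_REF})
        vb = VariantRecord("1", 2, "C", "T", genotypes={"x": HOM_REF})
        out = segregation_census(va, vb, ["x"])
        assert out["counts"]["WT/WT"] == 1

    def test_missing_genotype_reported_untyped(self):
        va = VariantRecord("1", 1, "A", "G", genotypes={"x": MISSING})
        vb = VariantRecord("1", 2, "C", "T", genotypes={"x": HET})
        out = segregation_census(va, vb, ["x"])
        assert out["counts"]["untyped"] == 1


class TestAncestorDeduction:
    def test_common_phantom_grandsire_is_obligate_carrier(self, fig2a):
        ped = fig2a["pedigree"]
        var_a = fig2a["var_a"]
        carrier_dams = [e for e in fig2a["ewes"]
                        if var_a.genotypes[e] == HET]
        out = deduce_ancestor_carrier(ped, var_a, carrier_dams)
        assert out["explanation"] == "single_ancestor"
        assert out["ancestors"] == ["GS"]
        assert "germline mosaic" in out["statement"]

    def test_disjoint_ancestry_has_no_single_explanation(self):
        ped = Pedigree([Individual("f1", sex="male"),
                        Individual("f2", sex="male"),
                        Individual("a", sire_id="f1", sex="female"),
                        Individual("b", sire_id="f2", sex="female")])
        v = VariantRecord("1", 1, "A", "G")
        out = deduce_ancestor_carrier(ped, v, ["a", "b"])
        assert out["explanation"] == "no_single_ancestor"

    def test_no_carriers_empty_statement(self):
        ped = Pedigree([Individual("x")])
        out = deduce_ancestor_carrier(ped, VariantRecord("1", 1, "A", "G"), [])
        assert out == {"explanation": "none", "ancestors": []}


class TestPrioritize:
    def test_funnel_fixture_ranks_causal_pair_first(self, funnel_fixture):
        fx = funnel_fixture
        res = run_funnel(fx["variants"], fx["trios"], fx["cases"],
                         fx["local"], fx["global"])
        rep = prioritize(res["final_calls"], fx["linked_regions"],
                         fx["shared_roh"])
        assert rep.candidates[0].call.gene_id == "geneC"
        assert rep.candidates[0].call.mode == "compound_het"
        decoy = next(c for c in rep.candidates if c.call.gene_id == "decoyR")
        assert "neither located in a linked genome region" in decoy.rationale

    def test_no_regions_falls_back_with_flag(self, funnel_fixture):
        fx = funnel_fixture
        res = run_funnel(fx["variants"], fx["trios"], fx["cases"],
                         fx["local"], fx["global"])
        rep = prioritize(res["final_calls"], None, None)
        assert rep.no_regions_supplied
        assert all("inheritance evidence alone" in c.rationale
                   for c in rep.candidates)


class TestFunnel:
    def test_funnel_is_monotone_and_logged(self, flock):
        res = run_funnel(flock.family_variants, flock.trios, flock.cases,
                         flock.local_controls, flock.global_controls)
        log = res["log"]
        order = ["input", "protein_changing", "private_vs_local",
                 "mode_fitting_local", "private_vs_global"]
        counts = [log[k] for k in order]
        assert counts == sorted(counts, reverse=True)
        assert all(v.key in {x.key for x in flock.family_variants}
                   for v in res["survivors"])
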