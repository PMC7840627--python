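import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from comphet import consequence as cq
from comphet.consequence import (TranscriptModel, annotate_all_isoforms,
                                 annotate_variant, apply_acceptor_loss,
                                 classify_snv, format_hgvs_c, format_hgvs_p,
                                 hgvs_c, map_genomic_to_cdna, parse_hgvs_c,
                                 parse_hgvs_p, translate_mutant)
from comphet.io_formats import VariantRecord


def _micro_gene(exon3_prefix, intron="GTAAACCCTTTAAACCCTTTAAACCCTTAG"):
    """3-exon forward gene with a configurable exon-3 start, for splice tests."""
    cds_codons = ["ATG"] + ["GCT"] * 9   # codons 1-10 in exons 1+2
    head = "".join(cds_codons)           # 30 nt
    e1, e2 = head[:12], head[12:]
    tail_codons = ["GAT"] * 20 + ["TAA"]  # GAT repeats contain no AG
    e3 = exon3_prefix + "".join(tail_codons)
    genome = e1 + intron + e2 + intron + e3
    exons = [(0, len(e1)),
             (len(e1) + len(intron), len(e1) + len(intron) + len(e2)),
             (len(genome) - len(e3), len(genome))]
    t = TranscriptModel("micro", "micro", "m", "+", exons, 0, len(genome),
                        seq={"m": genome})
    acc_pos = exons[2][0] - 2  # the acceptor A of intron 2
    var = VariantRecord("m", acc_pos, "A", "G")
    return t, var


class TestCoordinateMapping:
    def test_first_cds_base_is_c1(self, toys):
        t = toys.models["acceptor"]
        assert str(map_genomic_to_cdna(t.cds_start, t)) == "1"

    def test_acceptor_offset_c_n_minus_2(self, toys):
        t = toys.models["acceptor"]
        v = toys.variants["acceptor"]
        coord = map_genomic_to_cdna(v.pos, t)
        assert str(coord) == "210-2"
        assert hgvs_c(v, t) == "c.210-2A>G"

    def test_reverse_strand_alleles_complemented(self, toys):
        t = toys.models["acceptor_rev"]
        v = toys.variants["acceptor_rev"]
        assert (v.ref, v.alt) == ("T", "C")  # genomic alleles are flipped
        assert hgvs_c(v, t) == "c.210-2A>G"  # c. names are transcript-strand

    def test_utr_and_out_of_transcript(self, toys):
        t = toys.models["acceptor"]
        before = map_genomic_to_cdna(t.cds_start - 1, t)
        assert before.kind == "utr5" and str(before) == "-1"
        last = map_genomic_to_cdna(t.exons[-1][1] - 1, t)
        assert last.kind == "utr3" and str(last).startswith("*")
        out = map_genomic_to_cdna(t.exons[-1][1] + 500, t)
        assert out.kind == "out_of_transcript"


class TestClassifySnv:
    def test_nonsense_and_missense_isoform_pair(self, toys):
        v = toys.variants["iso"]
        assert classify_snv(v, toys.models["iso_short"]) == "nonsense"
        assert classify_snv(v, toys.models["iso_long"]) == "missense"

    def test_synonymous_wobble(self, toys):
        t = toys.models["acceptor"]
        # third base of codon 77 ("ACT" -> "ACC", both Thr): c.231
        g = t.exons[2][0] + 21  # c.210 is the exon-3 first base
        ref = t.chrom_seq()[g]
        assert ref == "T"
        v = VariantRecord("chrA", g, "T", "C")
        assert classify_snv(v, t) == "synonymous"

    def test_splice_region_not_protein_changing(self, toys):
        from comphet.variant_filter import PROTEIN_CHANGING
        t = toys.models["acceptor"]
        v = VariantRecord("chrA", t.exons[2][0] - 5, "N", "A")
        v.ref = t.chrom_seq()[v.pos]
        if v.ref == v.alt:
            v.alt = "C" if v.ref != "C" else "G"
        assert classify_snv(v, t) == "splice_region"
        assert "splice_region" not in PROTEIN_CHANGING

    def test_reference_mismatch_detected(self, toys):
        t = toys.models["acceptor"]
        wrong = "C" if t.chrom_seq()[t.cds_start] != "C" else "G"
        v = VariantRecord("chrA", t.cds_start, wrong, "T")
        with pytest.raises(cq.ConsequenceError, match="mismatch"):
            classify_snv(v, t)


class TestAcceptorLoss:
    def test_cryptic_ag_ten_base_deletion(self, toys):
        t, v = toys.models["acceptor"], toys.variants["acceptor"]
        rescue = apply_acceptor_loss(v, t)
        assert rescue.mode == "cryptic_acceptor"
        assert rescue.deletion_length == 10
        assert len(t.cds) - len(rescue.mutant_cds) == 10

    def test_exon_starting_with_ag_loses_two_bases(self):
        t, v = _micro_gene("AG" + "T")
        rescue = apply_acceptor_loss(v, t)
        assert rescue.mode == "cryptic_acceptor"
        assert rescue.deletion_length == 2

    def test_no_ag_in_window_skips_exon(self):
        t, v = _micro_gene("TTT")  # exon 3 tail is GAA repeats + TAA: no AG
        rescue = apply_acceptor_loss(v, t, scan_window=50)
        assert rescue.mode == "exon_skip"
        assert rescue.deletion_length == t.exons[2][1] - t.exons[2][0]

    def test_frameshift_iff_deletion_not_multiple_of_three(self, toys):
        t, v = toys.models["acceptor"], toys.variants["acceptor"]
        rescue = apply_acceptor_loss(v, t)
        assert len(t.cds) - len(rescue.mutant_cds) == rescue.deletion_length
        assert rescue.deletion_length % 3 != 0  # hence the frameshift call
        call = annotate_variant(v, t)
        assert "fsTer" in call.hgvs_p

    def test_non_acceptor_variant_rejected(self, toys):
        t = toys.models["acceptor"]
        v = VariantRecord("chrA", t.cds_start, t.chrom_seq()[t.cds_start],
                          "T" if t.chrom_seq()[t.cds_start] != "T" else "C")
        with pytest.raises(cq.ConsequenceError):
            apply_acceptor_loss(v, t)


class TestTranslateMutant:
    def test_engineered_frameshift_names_and_length(self, toys):
        call = annotate_variant(toys.variants["acceptor"],
                                toys.models["acceptor"])
        assert call.hgvs_p == "p.Leu71TrpfsTer3"
        assert call.mutant_protein_length == 72
        assert call.fraction_truncated > 0.9

    def test_identity(self):
        assert translate_mutant("ATGGCTTAA", "MA").hgvs_p == "p.(=)"
        assert translate_mutant("ATGGCTTAA", "MA").fraction_truncated == 0.0

    def test_stop_at_first_divergent_codon_is_nonsense_syntax(self):
        # reference MKL; mutant stops where K was
        mp = translate_mutant("ATGTAACTG", "MKL")
        assert mp.hgvs_p == "p.Lys2Ter"
        assert mp.mutant_protein_length == 1

    def test_no_stop_flagged(self):
        mp = translate_mutant("ATGGTTGTTGTT", "MA")
        assert mp.hgvs_p.endswith("Ter?") or mp.no_stop

    def test_agrees_with_codon_by_codon_oracle(self):
        """Frameshift naming against an independent codon-loop translator."""
        table = dict(standard_dna_table.forward_table)
        stops = set(standard_dna_table.stop_codons)

        def oracle_translate(cds):
            aa = []
            for k in range(0, len(cds) - 2, 3):
                codon = cds[k:k + 3]
                if codon in stops:
                    return "".join(aa), True
                aa.append(table[codon])
            return "".join(aa), False

        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        n_checked = 0
        for _ in range(300):
            ref_cds = "ATG" + "".join(
                rng.choice(bases, size=3 * rng.integers(10, 40))) + "TAA"
            ref_aa, stopped = oracle_translate(ref_cds)
            if not stopped or len(ref_aa) < 5:
                continue
            cut = int(rng.integers(4, len(ref_aa) * 3 - 3))
            mut_cds = ref_cds[:cut] + ref_cds[cut + 1:]  # 1-bp deletion
            mut_aa, _ = oracle_translate(mut_cds)
            mp = translate_mutant(mut_cds, ref_aa)
            assert mp.mutant_protein_length == len(mut_aa)
            n_checked += 1
        assert n_checked > 100


class TestIsoformAnnotation:
    def test_dual_call_missense_and_nonsense(self, toys):
        calls = annotate_all_isoforms(
            toys.variants["iso"],
            [toys.models["iso_short"], toys.models["iso_long"]])
        by_tx = {c.transcript_id: c for c in calls}
        assert by_tx["toyB.short"].effect_class == "nonsense"
        assert by_tx["toyB.short"].hgvs_p == "p.Gln396Ter"
        assert by_tx["toyB.short"].fraction_truncated == pytest.approx(0.5)
        assert by_tx["toyB.long"].effect_class == "missense"
        assert by_tx["toyB.long"].hgvs_p == "p.Leu396Phe"

    def test_insert_exon_variant_codes_only_on_long_isoform(self, toys):
        long = toys.models["iso_long"]
        ins = long.exons[3]
        g = ins[0] + 10
        ref = long.chrom_seq()[g]
        v = VariantRecord("chrB", g, ref, "A" if ref != "A" else "G")
        calls = annotate_all_isoforms(
            v, [toys.models["iso_short"], toys.models["iso_long"]])
        coding = [c for c in calls if c.effect_class not in
                  ("non_coding", "splice_region")]
        assert len(coding) == 1 and coding[0].transcript_id == "toyB.long"

    def test_deep_intronic_non_coding_everywhere(self, toys):
        short = toys.models["iso_short"]
        g = short.exons[0][1] + 40  # middle of intron 1
        ref = short.chrom_seq()[g]
        v = VariantRecord("chrB", g, ref, "A" if ref != "A" else "G")
        calls = annotate_all_isoforms(
            v, [toys.models["iso_short"], toys.models["iso_long"]])
        assert len(calls) == 2
        assert all(c.effect_class == "non_coding" for c in calls)


class TestStrandSymmetry:
    @pytest.mark.parametrize("fwd,rev,var_fwd,var_rev", [
        ("acceptor", "acceptor_rev", "acceptor", "acceptor_rev"),
        ("iso_short", "iso_short_rev", "iso", "iso_rev"),
        ("iso_long", "iso_long_rev", "iso", "iso_rev")])
    def test_reverse_mirror_gives_identical_calls(self, toys, fwd, rev,
                                                  var_fwd, var_rev):
        a = annotate_variant(toys.variants[var_fwd], toys.models[fwd])
        b = annotate_variant(toys.variants[var_rev], toys.models[rev])
        assert a.effect_class == b.effect_class
        assert a.hgvs_c == b.hgvs_c
        assert a.hgvs_p == b.hgvs_p
        assert a.mutant_protein_length == b.mutant_protein_length


class TestHgvsRoundTrip:
    @pytest.mark.parametrize("s", [
        "c.210-2A>G", "c.1186C>T", "c.1312C>T", "c.336-2A>G",
        "c.100+3A>G", "c.-5A>G", "c.*12C>T", "c.1A>T"])
    def test_c_names(self, s):
        assert format_hgvs_c(parse_hgvs_c(s)) == s

    @pytest.mark.parametrize("s", [
        "p.Leu71TrpfsTer3", "p.Gln396Ter", "p.Leu396Phe", "p.(=)",
        "p.Met1Val", "p.Ala5GlyfsTer12"])
    def test_p_names(self, s):
        assert format_hgvs_p(parse_hgvs_p(s)) == s

    def test_star_normalised_to_ter(self):
        parsed = parse_hgvs_p("p.Gln396*")
        assert format_hgvs_p(parsed) == "p.Gln396Ter"

    def test_emitted_names_round_trip(self, toys):
        for key, model_keys in (("acceptor", ["acceptor"]),
                                ("iso", ["iso_short", "iso_long"])):
            for mk in model_keys:
                call = annotate_variant(toys.variants[key], toys.models[mk])
                assert format_hgvs_c(parse_hgvs_c(call.hgvs_c)) == call.hgvs_c
                assert format_hgvs_p(parse_hgvs_p(call.hgvs_p)) == call.hgvs_p
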