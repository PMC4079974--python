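"""Consequence classification, transcript reconstruction, damage calls
and compensatory-pair detection."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from genarch import annotation as ann
from genarch.genes import (
    Gene,
    Transcript,
    make_toy_genes,
    patch_reference_for_gene,
    revcomp,
)
from genarch.types import HOM_ALT, HOM_REF, GenotypeMatrix, VariantRecord


@pytest.fixture(scope="module")
def toy():
    """Deterministic toy reference with a plus and a minus strand gene."""
    rng = np.random.default_rng(42)
    L = 12_000
    seq = bytearray(rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                               size=L).tobytes())
    genes = make_toy_genes("c", L, 4, rng)
    for g in genes:
        patch_reference_for_gene(seq, g)
    ref = {"c": seq.decode()}
    plus = next(g for g in genes if g.strand == "+")
    minus = next(g for g in genes if g.strand == "-")
    return ref, genes, plus, minus


def _mat(variants, calls_rows):
    calls = np.array(calls_rows, dtype=np.int8)
    return GenotypeMatrix([f"l{i}" for i in range(calls.shape[0])],
                          variants, calls)


class TestClassification:
    def test_one_bp_deletion_frameshift(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        p = int(np.sort(tx.cds_positions())[9])
        v = VariantRecord("c", p, ref["c"][p: p + 2], ref["c"][p], "del")
        calls = ann.classify_consequence(v, gene, ref["c"])
        assert {c.consequence for c in calls} == {"FRAME_SHIFT"}
        assert all(c.damaging for c in calls)

    def test_inframe_deletion_not_damaging(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        p = int(np.sort(tx.cds_positions())[9])
        v = VariantRecord("c", p, ref["c"][p: p + 4], ref["c"][p], "del")
        calls = ann.classify_consequence(v, gene, ref["c"])
        assert calls[0].consequence == "CODON_DELETION"
        assert not calls[0].damaging

    def test_splice_site_hit(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        s, e, kind = tx.splice_sites()[0]
        v = VariantRecord("c", s, ref["c"][s],
                          "A" if ref["c"][s] != "A" else "G")
        calls = ann.classify_consequence(v, gene, ref["c"])
        assert any(c.consequence.startswith("SPLICE_SITE")
                   for c in calls)

    def test_start_codon_disruption(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = tx.cds_positions()[0:3]
        p = int(pos[0]) if tx.strand == "+" else int(sorted(pos)[0])
        base = ref["c"][p]
        v = VariantRecord("c", p, base,
                          "C" if base != "C" else "T")
        calls = [c for c in ann.classify_consequence(v, gene, ref["c"])
                 if c.tx_id == tx.tx_id]
        assert calls[0].consequence == "START_LOST"

    def test_variant_on_wrong_contig_rejected(self, toy):
        _, _, gene, _ = toy
        v = VariantRecord("other", 10, "A", "G")
        with pytest.raises(ValueError):
            ann.classify_consequence(v, gene, "ACGT")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_snp_oracle_small_gene(self, strand):
        """Classifier agrees with direct translation of every possible
        SNP on a single-exon gene with a <= 60 bp CDS."""
        cds = "ATGGCTCATAAACTGGTCGATTGCCGTTAA"  # 10 codons, no stops
        if strand == "+":
            seq = "G" * 10 + cds + "G" * 10
            cds_span = (10, 10 + len(cds))
        else:
            seq = "G" * 10 + revcomp(cds) + "G" * 10
            cds_span = (10, 10 + len(cds))
        tx = Transcript("t", "c", strand, [(5, len(seq) - 2)], cds_span)
        gene = Gene("g", "c", [tx])
        assert tx.cds_sequence(seq) == cds
        ref_prot = str(Seq(cds).translate())
        for p in range(cds_span[0], cds_span[1]):
            for alt in "ACGT":
                if alt == seq[p]:
                    continue
                v = VariantRecord("c", p, seq[p], alt)
                got = ann.classify_consequence(v, gene, seq)[0]
                var_cds = ann.apply_variants_to_transcript(tx, seq, [v])
                var_prot = str(Seq(var_cds).translate())
                i = (p - cds_span[0] if strand == "+"
                     else cds_span[1] - 1 - p)
                ci = i // 3
                if ci == 0 and var_cds[0:3] != "ATG":
                    expected = "START_LOST"
                elif ci == len(cds) // 3 - 1 and var_prot[-1] != "*":
                    expected = "STOP_LOST"
                elif "*" in var_prot[:-1]:
                    expected = "STOP_GAINED"
                elif var_prot == ref_prot:
                    expected = "SYNONYMOUS"
                else:
                    expected = "MISSENSE"
                assert got.consequence == expected, (p, alt)


class TestTranscriptReconstruction:
    def test_no_variants_identity(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        assert ann.apply_variants_to_transcript(tx, ref["c"], []) \
            == tx.cds_sequence(ref["c"])

    def test_two_snps_two_differences(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = np.sort(tx.cds_positions())
        vs = []
        for p in (int(pos[6]), int(pos[12])):
            b = ref["c"][p]
            vs.append(VariantRecord("c", p, b,
                                    "A" if b != "A" else "T"))
        out = ann.apply_variants_to_transcript(tx, ref["c"], vs)
        refcds = tx.cds_sequence(ref["c"])
        assert len(out) == len(refcds)
        assert sum(x != y for x, y in zip(out, refcds)) == 2

    def test_net_zero_indels_preserve_length(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = np.sort(tx.cds_positions())
        p1, p2 = int(pos[6]), int(pos[20])
        s = ref["c"]
        vs = [VariantRecord("c", p1, s[p1], s[p1] + "A", "ins"),
              VariantRecord("c", p2, s[p2: p2 + 2], s[p2], "del")]
        out = ann.apply_variants_to_transcript(tx, s, vs)
        assert len(out) == len(tx.cds_sequence(s))

    def test_overlapping_variants_rejected(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        p = int(np.sort(tx.cds_positions())[6])
        s = ref["c"]
        vs = [VariantRecord("c", p, s[p: p + 4], s[p], "del"),
              VariantRecord("c", p + 2, s[p + 2], "A")]
        with pytest.raises(ValueError, match="overlapping"):
            ann.apply_variants_to_transcript(tx, s, vs)


class TestTranslate:
    @pytest.mark.parametrize("cds, prot", [
        ("ATGAAATAA", "MK"),
        ("ATGTAA", "M"),
        ("ATGAA", "M"),  # trailing partial codon dropped
    ])
    def test_examples(self, cds, prot):
        assert ann.translate(cds) == prot

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ann.translate("AT")


class TestGlobalIdentity:
    def test_identical(self):
        assert ann.global_identity("MKLV", "MKLV") == 100.0

    def test_symmetric(self):
        a, b = "MKLVANDPEWRT", "MKLANDPEWRT"
        assert ann.global_identity(a, b) == pytest.approx(
            ann.global_identity(b, a))

    def test_truncated_product_below_threshold(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        prot = ann.translate(tx.cds_sequence(ref["c"]))
        assert ann.global_identity(prot, prot[:len(prot) // 5]) < 90

    def test_empty_is_zero(self):
        assert ann.global_identity("", "MK") == 0.0


class TestGeneDamage:
    def test_early_frameshift_damages_single_transcript_gene(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        p = int(np.sort(tx.cds_positions())[9])
        v = VariantRecord("c", p, ref["c"][p: p + 2], ref["c"][p], "del")
        m = _mat([v], [[HOM_ALT], [HOM_REF]])
        single = Gene(gene.gene_id, gene.contig, [tx])
        rep = ann.gene_damage("l0", single, m, ref)
        assert rep.damaged
        assert rep.identity < 90
        assert not ann.gene_damage("l1", single, m, ref).damaged

    def test_synonymous_only_line_undamaged(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        # build a variant verified synonymous against transcript 1
        s = ref["c"]
        v = None
        for p in map(int, np.sort(tx.cds_positions())[12:60]):
            for alt in "ACGT":
                if alt == s[p]:
                    continue
                cand = VariantRecord("c", p, s[p], alt)
                calls = ann.classify_consequence(cand, gene, s)
                if {c.consequence for c in calls} == {"SYNONYMOUS"}:
                    v = cand
                    break
            if v:
                break
        assert v is not None
        m = _mat([v], [[HOM_ALT]])
        rep = ann.gene_damage("l0", gene, m, ref)
        assert rep.identity == 100.0
        assert not rep.damaged

    def test_all_transcripts_rule(self, toy):
        """A variant knocking out only one of two splice variants does
        not damage the gene."""
        ref, genes, _, _ = toy
        two_tx = next((g for g in genes if len(g.transcripts) == 2),
                      None)
        if two_tx is None:
            pytest.skip("toy draw produced no two-transcript gene")
        t1, t2 = two_tx.transcripts
        only_t1 = sorted(set(map(int, t1.cds_positions()))
                         - set(map(int, t2.cds_positions())))
        assert only_t1, "transcripts do not differ"
        p = only_t1[len(only_t1) // 2]
        v = VariantRecord("c", p, ref["c"][p: p + 2], ref["c"][p],
                          "del")
        m = _mat([v], [[HOM_ALT]])
        rep = ann.gene_damage("l0", two_tx, m, ref)
        verdicts = {vd.tx_id: vd.damaged for vd in rep.verdicts}
        assert verdicts[t1.tx_id]
        assert not verdicts[t2.tx_id]
        assert not rep.damaged


class TestDamageSummary:
    def test_no_damage(self):
        reports = [ann.DamageReport("l0", "g0",
                                    [ann.TranscriptVerdict("t", False,
                                                           False, 100.0)])]
        lpg, gpl, totals = ann.damage_summary(reports)
        assert totals["n_damaged_genes"] == 0
        assert lpg.empty

    def test_counts(self, toy):
        reports = []
        for i in range(10):
            damaged = i < 3
            reports.append(ann.DamageReport(
                f"l{i}", "g0",
                [ann.TranscriptVerdict("t", damaged, False, 100.0)]))
        lpg, gpl, totals = ann.damage_summary(reports)
        assert totals["n_damaged_genes"] == 1
        assert lpg.loc[3] == 1  # one gene damaged in exactly 3 lines
        assert totals["mean_damaged_genes_per_line"] == pytest.approx(0.3)


class TestCompensatoryPairs:
    def test_planted_frame_pair_found(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = np.sort(tx.cds_positions())
        p1, p2 = int(pos[10]), int(pos[14])
        s = ref["c"]
        v1 = VariantRecord("c", p1, s[p1], s[p1] + "G", "ins")
        v2 = VariantRecord("c", p2, s[p2: p2 + 2], s[p2], "del")
        m = _mat([v1, v2],
                 [[HOM_ALT, HOM_ALT], [HOM_REF, HOM_REF],
                  [HOM_REF, HOM_REF]])
        single = Gene(gene.gene_id, gene.contig, [tx])
        pairs = ann.find_compensatory_pairs(m, [single], ref)
        assert len(pairs) == 1
        assert pairs[0].mechanism == "frame_restoring_indels"
        assert pairs[0].D_prime == pytest.approx(1.0)

    def test_lone_frameshift_no_pair(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        p = int(np.sort(tx.cds_positions())[10])
        s = ref["c"]
        v = VariantRecord("c", p, s[p], s[p] + "G", "ins")
        m = _mat([v], [[HOM_ALT], [HOM_REF]])
        assert ann.find_compensatory_pairs(
            m, [Gene(gene.gene_id, gene.contig, [tx])], ref) == []

    def test_discordant_carriers_no_pair(self, toy):
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = np.sort(tx.cds_positions())
        p1, p2 = int(pos[10]), int(pos[14])
        s = ref["c"]
        v1 = VariantRecord("c", p1, s[p1], s[p1] + "G", "ins")
        v2 = VariantRecord("c", p2, s[p2: p2 + 2], s[p2], "del")
        m = _mat([v1, v2],
                 [[HOM_ALT, HOM_REF], [HOM_REF, HOM_ALT]])
        assert ann.find_compensatory_pairs(
            m, [Gene(gene.gene_id, gene.contig, [tx])], ref) == []

    def test_frame_pair_identity_at_least_single(self, toy):
        """Applying the restoring pair yields a protein at least as
        close to the reference as either frameshift alone."""
        ref, _, gene, _ = toy
        tx = gene.transcripts[0]
        pos = np.sort(tx.cds_positions())
        p1, p2 = int(pos[10]), int(pos[16])
        s = ref["c"]
        v1 = VariantRecord("c", p1, s[p1], s[p1] + "G", "ins")
        v2 = VariantRecord("c", p2, s[p2: p2 + 2], s[p2], "del")
        ref_prot = ann.translate(tx.cds_sequence(s))
        def ident(vs):
            return ann.global_identity(
                ref_prot,
                ann.translate(ann.apply_variants_to_transcript(tx, s, vs)))
        joint = ident([v1, v2])
        assert joint >= ident([v1]) - 1e-9
        assert joint >= ident([v2]) - 1e-9

    def test_stop_rescue_pair(self):
        """A premature-stop SNP present only in lines carrying a rescuer
        in the same codon is reported as a rescue pair."""
        # codon 2 = CAA; A->T at its first base gives TAA (stop);
        # a second SNP A->G at base 2 gives TGA?... choose rescuer at
        # base 3: TAA -> TAG still stop, so rescue at base 2: TCA (Ser)
        cds = "ATGCAAAAACTGGTCGATTGCCGTTAA"
        seq = "GGGGG" + cds + "GGGGG"
        tx = Transcript("t", "c", "+", [(2, len(seq) - 2)],
                        (5, 5 + len(cds)))
        gene = Gene("g", "c", [tx])
        stop = VariantRecord("c", 8, "C", "T")   # CAA -> TAA
        rescue = VariantRecord("c", 9, "A", "C")  # TAA -> TCA with stop
        m = _mat([stop, rescue],
                 [[HOM_ALT, HOM_ALT], [HOM_REF, HOM_ALT],
                  [HOM_REF, HOM_REF]])
        pairs = ann.find_compensatory_pairs(m, [gene], {"c": seq})
        mechs = {p.mechanism for p in pairs}
        assert "stop_rescuing_snp" in mechs
        hit = next(p for p in pairs
                   if p.mechanism == "stop_rescuing_snp")
        assert {hit.vid_a, hit.vid_b} == {stop.vid, rescue.vid}
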