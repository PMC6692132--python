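"""Mutation classification and codon-level covariates."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutdfe.mutations import (BACTERIAL_TABLE, CodingSequence, CodonUsageTable,
                              MutationClass, MrnaWindow, PointMutation,
                              ReferenceMismatchError, TRNACopyTable,
                              classify_mutation, compute_cai, compute_tai,
                              delta_metrics, extract_mrna_window, ramp_test)

SENSE = sorted(BACTERIAL_TABLE.forward_table)
STOPS = set(BACTERIAL_TABLE.stop_codons)


def _aa(codon):
    return "*" if codon in STOPS else BACTERIAL_TABLE.forward_table[codon]


class TestClassify:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (6, "T", "C", MutationClass.SYNONYMOUS),      # GGT -> GGC
        (18, "G", "A", MutationClass.NONSENSE),       # TGG -> TGA
        (5, "G", "A", MutationClass.NONSYNONYMOUS),   # GGT -> GAT, G->D
    ])
    def test_examples(self, toy_cds, pos, ref, alt, expected):
        mut = PointMutation(cds_position=pos, ref_base=ref, alt_base=alt)
        assert classify_mutation(toy_cds, mut) == expected

    def test_exhaustive_codon_substitution_oracle(self):
        """Every substitution in every sense codon agrees with brute-force
        translation of the mutant codon."""
        for codon in SENSE:
            cds = CodingSequence(id="x", seq="ATG" + codon + "CGT" + "TAA")
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mutant = codon[:i] + alt + codon[i + 1:]
                    got = classify_mutation(cds, PointMutation(
                        cds_position=4 + i, ref_base=codon[i], alt_base=alt))
                    if mutant in STOPS:
                        expected = MutationClass.NONSENSE
                    elif _aa(mutant) == _aa(codon):
                        expected = MutationClass.SYNONYMOUS
                    else:
                        expected = MutationClass.NONSYNONYMOUS
                    assert got == expected, (codon, i, alt)

    def test_reference_mismatch_and_range_errors(self, toy_cds):
        with pytest.raises(ReferenceMismatchError):
            classify_mutation(toy_cds, PointMutation(6, "A", "C"))
        with pytest.raises(ValueError):
            classify_mutation(toy_cds, PointMutation(999, "A", "C"))
        # terminal stop codon is not a sense codon
        with pytest.raises(ValueError):
            classify_mutation(toy_cds, PointMutation(34, "T", "C"))

    def test_labels(self, toy_cds):
        mut = PointMutation(6, "T", "C")
        assert mut.codon_index == 2 and mut.codon_position == 3
        assert mut.site_label == "2-3C"
        assert mut.protein_label(toy_cds) == "G2G"


class TestCAI:
    def test_all_preferred_codons_give_one(self, usage_table):
        gene = "GGT" * 10 + "CTG" * 5
        cai, _ = compute_cai(gene, usage_table)
        assert cai == pytest.approx(1.0)

    def test_single_swap_closed_form(self, usage_table):
        """One codon swap changes CAI by (w_new/w_old)^(1/L)."""
        gene = ["GGT"] * 10 + ["CTG"] * 10
        before, _ = compute_cai(gene, usage_table)
        after, _ = compute_cai(["GGC"] + gene[1:], usage_table)
        w_new = usage_table.weight("GGC")
        w_old = usage_table.weight("GGT")
        assert after / before == pytest.approx((w_new / w_old) ** (1 / 20))

    def test_matches_bruteforce_loop(self, usage_table):
        rng = np.random.default_rng(3)
        codons = [SENSE[i] for i in rng.integers(0, len(SENSE), 100)]
        cai, _ = compute_cai(codons, usage_table)
        logs = [math.log(usage_table.weight(c)) for c in codons
                if c not in ("ATG", "TGG")]
        assert cai == pytest.approx(math.exp(sum(logs) / len(logs)))

    @given(st.randoms(use_true_random=False))
    def test_permutation_invariant(self, usage_table, rnd):
        codons = ["GGT", "GGC", "CTG", "TTA", "AAA", "CGT"] * 3
        base, _ = compute_cai(codons, usage_table)
        shuffled = codons[:]
        rnd.shuffle(shuffled)
        perm, _ = compute_cai(shuffled, usage_table)
        assert perm == pytest.approx(base)
        assert 0 < base <= 1

    def test_empty_included_set_errors(self, usage_table):
        with pytest.raises(ValueError):
            compute_cai(["ATG", "TGG"], usage_table)


class TestTAI:
    def test_single_trna_single_codon(self):
        table = TRNACopyTable({"ACC": 3})    # decodes GGT (and GGC by wobble)
        tai, _ = compute_tai(["GGT", "GGT"], table)
        assert tai == pytest.approx(1.0)

    def test_copy_number_scale_invariance(self, trna_table):
        doubled = TRNACopyTable({a: 2 * n for a, n in trna_table.copies.items()})
        seq = ["GGT", "GGC", "CTG", "AAA"] * 3
        t1, _ = compute_tai(seq, trna_table)
        t2, _ = compute_tai(seq, doubled)
        assert t2 == pytest.approx(t1)

    def test_hand_computed_toy(self, trna_table):
        """Independent loop over the wobble rules for a 10-codon sequence."""
        s = {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68, "L:A": 0.89}
        copies = trna_table.copies
        # GGT: WC anticodon ACC (4 copies) + G:U wobble from GCC (2 copies)
        W_ggt = 4 + (1 - s["G:U"]) * 2
        # GGC: WC GCC (2) + I:C from ACC (4)
        W_ggc = 2 + (1 - s["I:C"]) * 4
        # CTG: WC CAG (1) + U:G from TAG (0)
        W_ctg = 1.0
        W = trna_table.absolute_adaptiveness()
        assert W["GGT"] == pytest.approx(W_ggt)
        assert W["GGC"] == pytest.approx(W_ggc)
        assert W["CTG"] == pytest.approx(W_ctg)
        rel = trna_table.relative_weights()
        top = max(W.values())
        nonzero = [w / top for w in W.values() if w > 0]
        gm = math.exp(np.mean(np.log(nonzero)))
        seq = ["GGT"] * 4 + ["GGC"] * 3 + ["CTG"] * 2 + ["AAA"]  # AAA undecoded
        expected = math.exp(np.mean(np.log(
            [W_ggt / top] * 4 + [W_ggc / top] * 3 + [W_ctg / top] * 2 + [gm])))
        tai, _ = compute_tai(seq, trna_table)
        assert tai == pytest.approx(expected)
        assert 0 < tai <= 1

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            TRNACopyTable({}).absolute_adaptiveness()


class TestDeltaMetrics:
    def test_equal_weight_synonymous_swap_is_zero(self, trna_table):
        usage = CodonUsageTable.from_counts({})   # all weights 1 after smoothing
        cds = CodingSequence(id="x", seq="ATGGGTGGCCTGAAATAA")
        mut = PointMutation(6, "T", "C")          # GGT -> GGC, both weight 1
        d = delta_metrics(cds, mut, usage, trna_table)
        assert d["delta_cai"] == pytest.approx(0.0)

    def test_distance_zero_at_first_base(self, toy_cds, usage_table, trna_table):
        d = delta_metrics(toy_cds, PointMutation(1, "A", "C"),
                          usage_table, trna_table)
        assert d["distance_from_start_nt"] == 0
        assert d["codon_index"] == 1

    def test_delta_equals_independent_recompute(self, toy_cds, usage_table,
                                                trna_table):
        mut = PointMutation(6, "T", "C")
        d = delta_metrics(toy_cds, mut, usage_table, trna_table)
        mutant = toy_cds.with_substitution(6, "C")
        assert d["delta_cai"] == pytest.approx(
            compute_cai(mutant, usage_table)[0] - compute_cai(toy_cds, usage_table)[0])
        assert d["delta_tai"] == pytest.approx(
            compute_tai(mutant, trna_table)[0] - compute_tai(toy_cds, trna_table)[0])

    def test_nonsense_rejected(self, toy_cds, usage_table, trna_table):
        with pytest.raises(ValueError):
            delta_metrics(toy_cds, PointMutation(18, "G", "A"),
                          usage_table, trna_table)


class TestMrnaWindow:
    def test_stated_coordinates(self):
        body = "GGTGCA" * 40
        cds = CodingSequence(id="x", seq="ATG" + body + "TAA")
        mut = PointMutation(100, cds.seq[99], "A" if cds.seq[99] != "A" else "C")
        win = extract_mrna_window(cds, mut, width=42)
        assert win.start == 79
        assert len(win.reference) == 42
        assert win.start + 41 == 120
        assert win.mutation_offset == 21
        diffs = [i for i, (a, b) in enumerate(zip(win.reference, win.mutant))
                 if a != b]
        assert diffs == [21]

    def test_truncation_flagged(self):
        cds = CodingSequence(id="x", seq="ATG" + "GGTGCA" * 9 + "TAA")  # no flanks
        mut = PointMutation(5, cds.seq[4], "A")
        win = extract_mrna_window(cds, mut, width=42)
        assert win.truncated_left and not win.truncated_right
        assert win.reference[win.mutation_offset] == cds.seq[4]

    def test_flanks_fill_window(self, toy_cds):
        mut = PointMutation(6, "T", "C")
        win = extract_mrna_window(toy_cds, mut, width=20)
        assert not win.truncated_left
        full = toy_cds.flank5 + toy_cds.seq
        assert win.reference == full[len(toy_cds.flank5) + 5 - 10:
                                     len(toy_cds.flank5) + 5 + 10]


class TestRampTest:
    def test_constant_weights_null(self):
        usage = CodonUsageTable.from_counts({})   # every weight 1
        cds = CodingSequence(id="x", seq="ATG" + "GGT" * 70 + "TAA")
        res = ramp_test(cds, usage, B=200, seed=0)
        assert res.slope == pytest.approx(0.0)
        assert res.p_slope > 0.9

    def test_planted_ramp_detected(self, usage_table):
        # rare codons (low weight) in the first 50 codons, preferred after
        cds = CodingSequence(id="x", seq="ATG" + "GGG" * 50 + "GGT" * 50 + "TAA")
        res = ramp_test(cds, usage_table, B=500, seed=0)
        # the planted signal: early mean far below late mean, group p tiny
        assert res.first50_mean < res.rest_mean
        assert res.p_group < 1e-6
        # and the regression slope is positive (weights rise along the gene)
        assert res.slope > 0
        assert res.p_slope == pytest.approx(1 / 501, abs=1e-3)

    def test_short_gene_skips_group_comparison(self, usage_table):
        cds = CodingSequence(id="x", seq="ATG" + "GGT" * 20 + "TAA")
        with pytest.warns(UserWarning):
            res = ramp_test(cds, usage_table, B=100, seed=0)
        assert res.p_group is None
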