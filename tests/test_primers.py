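"""Primer design and in-silico PCR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsort.primers import (
    DesignConstraints,
    PcrParams,
    Primer,
    PrimerError,
    PrimerPair,
    conserved_runs,
    design_primers,
    insilico_pcr,
    melting_temp,
    specificity_matrix,
)
from strainsort.seqio import GenomeRecord, reverse_complement

from conftest import random_seq


class TestMeltingTemp:
    def test_wallace_rule_short(self):
        assert melting_temp("AATT", "wallace", enforce_length=False) == 8.0

    def test_wallace_rule_gc(self):
        assert melting_temp("GGCCGGCC", "wallace") == 32.0

    def test_non_acgt_rejected(self):
        with pytest.raises(PrimerError):
            melting_temp("ACGU")

    def test_length_guard(self):
        with pytest.raises(PrimerError):
            melting_temp("ACGTACG", "wallace")

    def test_nn_close_to_wallace_for_balanced_20mers(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            while True:
                s = random_seq(rng, 20)
                gc = (s.count("G") + s.count("C")) / 20
                if 0.40 <= gc <= 0.60:
                    break
            assert abs(melting_temp(s, "nn") - melting_temp(s, "wallace")) < 8.0


class TestConservedRuns:
    def test_full_conservation(self):
        assert conserved_runs(["ACGT", "ACGT"]) == [(0, 4)]

    def test_variable_column_splits_runs(self):
        runs = conserved_runs(["ACGTACGT", "ACGAACGT"])
        assert runs == [(0, 3), (4, 8)]

    def test_gap_column_breaks_run(self):
        runs = conserved_runs(["ACG-T", "ACGAT"])
        # the gap column is skipped in target coordinates
        assert runs == [(0, 3), (3, 4)]


class TestDesignPrimers:
    def test_conserved_639bp_target_yields_pairs(self):
        rng = np.random.default_rng(29)
        target = random_seq(rng, 639)
        res = design_primers(target)
        assert res.pairs
        top = res.pairs[0]
        assert top.designed_product <= 639
        assert 18 <= top.forward.length <= 28
        assert 0.40 <= top.forward.gc <= 0.60
        assert abs(top.forward.tm - top.reverse.tm) <= 5.0
        # the reverse primer is the reverse complement of a target window
        assert reverse_complement(top.reverse.sequence) in target

    def test_target_shorter_than_product_rejected(self):
        with pytest.raises(PrimerError):
            design_primers("ACGT" * 30)  # 120 bp < product_min

    def test_variable_columns_everywhere_gives_empty(self):
        rng = np.random.default_rng(31)
        target = random_seq(rng, 400)
        # a homolog differing every ~10 bp leaves no 18-bp conserved window
        other = list(target)
        for pos in range(0, 400, 10):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        res = design_primers(target, [target, "".join(other)])
        assert res.pairs == []
        assert res.diagnostics["candidate_windows"] == 0

    def test_determinism(self):
        rng = np.random.default_rng(37)
        target = random_seq(rng, 500)
        r1 = design_primers(target)
        r2 = design_primers(target)
        assert [(p.forward.sequence, p.reverse.sequence) for p in r1.pairs[:5]] == [
            (p.forward.sequence, p.reverse.sequence) for p in r2.pairs[:5]
        ]


def make_pair(f, r, lo=50, hi=2000):
    return PrimerPair(
        forward=Primer("F", f), reverse=Primer("R", r), expected_product_range=(lo, hi)
    )


class TestInsilicoPcr:
    def test_constructed_template_product_length(self):
        rng = np.random.default_rng(41)
        f = random_seq(rng, 20)
        r = random_seq(rng, 22)
        template = random_seq(rng, 100) + f + random_seq(rng, 580) + reverse_complement(r) + random_seq(rng, 100)
        g = GenomeRecord("t", [("c", template)])
        hits = insilico_pcr(g, make_pair(f, r))
        assert len(hits) == 1
        assert hits[0].product_length == 20 + 580 + 22
        assert hits[0].forward_site.start == 101

    def test_forward_without_reverse_is_negative(self):
        rng = np.random.default_rng(43)
        f = random_seq(rng, 20)
        r = random_seq(rng, 20)
        g = GenomeRecord("t", [("c", random_seq(rng, 200) + f + random_seq(rng, 400))])
        assert insilico_pcr(g, make_pair(f, r)) == []

    def test_3prime_mismatch_blocks_amplification(self):
        rng = np.random.default_rng(47)
        f = random_seq(rng, 20)
        r = random_seq(rng, 20)
        # mutate the base pairing with R's 3'-terminal position
        site = list(reverse_complement(r))
        site[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[0]]
        template = random_seq(rng, 50) + f + random_seq(rng, 300) + "".join(site) + random_seq(rng, 50)
        g = GenomeRecord("t", [("c", template)])
        assert insilico_pcr(g, make_pair(f, r), PcrParams(max_mismatch=1, require_exact_3prime=1)) == []
        hits = insilico_pcr(g, make_pair(f, r), PcrParams(max_mismatch=1, require_exact_3prime=0))
        assert len(hits) == 1

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_product_length_equals_construction(self, seed):
        rng = np.random.default_rng(seed)
        f = random_seq(rng, int(rng.integers(18, 26)))
        r = random_seq(rng, int(rng.integers(18, 26)))
        spacer = int(rng.integers(0, 400))
        template = (
            random_seq(rng, int(rng.integers(0, 80)))
            + f
            + random_seq(rng, spacer)
            + reverse_complement(r)
            + random_seq(rng, int(rng.integers(0, 80)))
        )
        g = GenomeRecord("t", [("c", template)])
        hits = insilico_pcr(g, make_pair(f, r, lo=1, hi=10_000), PcrParams(max_mismatch=0))
        expected = len(f) + spacer + len(r)
        assert expected in [h.product_length for h in hits]

    def test_exact_mode_equals_string_search(self):
        # with no mismatch budget a site exists iff the primer (or its
        # reverse complement) occurs literally
        rng = np.random.default_rng(53)
        params = PcrParams(max_mismatch=0, require_exact_3prime=0)
        for _ in range(200):
            f = random_seq(rng, 12)
            r = random_seq(rng, 12)
            template = random_seq(rng, 600)
            if rng.random() < 0.5:  # plant sites in half the templates
                i = int(rng.integers(0, 200))
                j = int(rng.integers(300, 500))
                template = template[:i] + f + template[i + 12 : j] + reverse_complement(r) + template[j + 12 :]
            g = GenomeRecord("t", [("c", template)])
            got = {
                (h.forward_site.start, h.reverse_site.start, h.product_length)
                for h in insilico_pcr(g, make_pair(f, r, lo=1, hi=10_000), params)
            }
            expected = set()
            for left, right in ((f, r), (r, f)):
                lpos = [k for k in range(len(template) - len(left) + 1)
                        if template[k : k + len(left)] == left]
                rc = reverse_complement(right)
                rpos = [k for k in range(len(template) - len(right) + 1)
                        if template[k : k + len(right)] == rc]
                for i in lpos:
                    for j in rpos:
                        if j >= i + len(left):
                            expected.add((i + 1, j + 1, j + len(right) - i))
            assert got == expected


class TestSpecificityMatrix:
    def test_empty_panel_rejected(self):
        with pytest.raises(PrimerError):
            specificity_matrix([], make_pair("A" * 20, "C" * 20))

    def test_self_template_positive(self):
        rng = np.random.default_rng(59)
        f = random_seq(rng, 20)
        r = random_seq(rng, 20)
        g = GenomeRecord("t", [("c", f + random_seq(rng, 300) + reverse_complement(r))])
        rows = specificity_matrix([g], make_pair(f, r))
        assert rows[0].positive and not rows[0].multi_band

    def test_planted_marker_separates_panel(self, small_panel):
        planted = small_panel.truth.planted_gene_id
        copies = [
            next(g for g in small_panel.annotations[sid] if g.gene_id == planted).sequence
            for sid in sorted(
                small_panel.truth.carriers,
                key=lambda s: (s != "IN01", s),  # design target first
            )
        ]
        # no indels in the simulation, so the copies are already aligned;
        # designing on their conserved windows guarantees perfect primer
        # sites in every carrier
        res = design_primers(copies[0], copies)
        assert res.pairs
        rows = specificity_matrix(small_panel.genomes, res.pairs[0], PcrParams())
        positives = {r.genome_id for r in rows if r.positive}
        assert positives == set(small_panel.truth.carriers)
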