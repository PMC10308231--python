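"""RBH orthology, orthogroup components and the diagnostic screen."""

import numpy as np
import pytest

from strainsort import synthetic as sy
from strainsort.orthologs import (
    OrthologyError,
    PresenceParams,
    build_orthogroups,
    conservation_filter,
    presence_by_search,
    protein_rbh,
    screen_core_unique,
)
from strainsort.seqio import GenomeRecord

from conftest import random_seq


def proteome(rng, n_genes, length=250, prefix="g"):
    return [
        (f"{prefix}{i}", random_seq(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"))
        for i in range(n_genes)
    ]


class TestProteinRbh:
    def test_identical_proteomes_perfect_matching(self):
        rng = np.random.default_rng(1)
        p = proteome(rng, 8)
        pairs = protein_rbh(p, p)
        assert pairs == [(g, g) for g, _ in p]

    def test_duplicated_gene_is_ambiguous(self):
        rng = np.random.default_rng(2)
        p = proteome(rng, 4)
        dup = p + [("dup", p[0][1])]  # identical copy of g0
        pairs = protein_rbh(p, dup)
        assert all(ga != "g0" for ga, _ in pairs)
        assert len(pairs) == 3

    def test_empty_proteome_rejected(self):
        with pytest.raises(OrthologyError):
            protein_rbh([], [("a", "MKV")])

    def test_divergent_orthologs_recovered(self, small_panel):
        pa = small_panel.proteome("IN01")
        po = small_panel.proteome("OUT01")
        pairs = protein_rbh(pa, po)
        true_shared = {g for g, _ in po}
        recovered = {ga for ga, gb in pairs if ga == gb}
        assert len(recovered) >= 0.95 * len(true_shared)


class TestBuildOrthogroups:
    def test_transitive_closure(self):
        proteomes = {
            "A": [("g1", "M" * 30)],
            "B": [("g2", "M" * 30)],
            "C": [("g3", "M" * 30)],
        }
        rbh = {
            ("A", "B"): [("g1", "g2")],
            ("B", "C"): [("g2", "g3")],
            ("A", "C"): [],
        }
        og = build_orthogroups(proteomes, rbh)
        sizes = sorted(len(m) for _, m in og.groups)
        assert sizes == [3]

    def test_unmatched_gene_becomes_singleton(self):
        proteomes = {
            "A": [("g1", "M" * 30), ("solo", "W" * 30)],
            "B": [("g2", "M" * 30)],
        }
        og = build_orthogroups(proteomes, {("A", "B"): [("g1", "g2")]})
        by_size = sorted(og.groups, key=lambda g: -len(g[1]))
        assert len(by_size[0][1]) == 2
        assert by_size[1][1] == frozenset({("A", "solo")})

    def test_missing_pair_is_an_error(self):
        proteomes = {"A": [("g1", "M" * 30)], "B": [("g2", "M" * 30)], "C": []}
        with pytest.raises(OrthologyError, match="missing RBH"):
            build_orthogroups(proteomes, {("A", "B"): []})

    def test_groups_partition_all_genes(self, small_panel):
        strains = ["IN01", "IN02", "OUT01"]
        proteomes = {s: small_panel.proteome(s) for s in strains}
        rbh = {}
        for i, a in enumerate(strains):
            for b in strains[i + 1 :]:
                rbh[(a, b)] = protein_rbh(proteomes[a], proteomes[b])
        og = build_orthogroups(proteomes, rbh)
        all_genes = {(s, g) for s, p in proteomes.items() for g, _ in p}
        seen = [m for _, members in og.groups for m in members]
        assert sorted(seen) == sorted(all_genes)  # no gene twice, none lost


def _toy_groups():
    proteomes = {
        "I1": [("core", "M" * 30), ("diag", "W" * 30)],
        "I2": [("core", "M" * 30), ("diag", "W" * 30)],
        "O1": [("core", "M" * 30)],
        "O2": [("core", "M" * 30)],
    }
    rbh = {
        ("I1", "I2"): [("core", "core"), ("diag", "diag")],
        ("I1", "O1"): [("core", "core")],
        ("I1", "O2"): [("core", "core")],
        ("I2", "O1"): [("core", "core")],
        ("I2", "O2"): [("core", "core")],
        ("O1", "O2"): [("core", "core")],
    }
    seqs = {(g, n): "ATG" + "CAG" * 20 for g in proteomes for n, _ in proteomes[g]}
    return build_orthogroups(proteomes, rbh), seqs


class TestScreenCoreUnique:
    def test_ingroup_only_group_is_candidate(self):
        og, seqs = _toy_groups()
        cands = screen_core_unique(og, ["I1", "I2"], ["O1", "O2"], seqs)
        assert len(cands) == 1
        assert cands[0].gene_id == "diag"
        assert cands[0].genome_id == "I1"  # smallest in-group genome

    def test_universal_group_excluded(self):
        og, seqs = _toy_groups()
        cands = screen_core_unique(og, ["I1", "I2"], ["O1", "O2"], seqs)
        assert all(c.gene_id != "core" for c in cands)

    def test_overlapping_panels_rejected(self):
        og, seqs = _toy_groups()
        with pytest.raises(OrthologyError, match="overlap"):
            screen_core_unique(og, ["I1", "I2"], ["I2", "O1"], seqs)

    def test_adding_outgroup_genomes_never_adds_candidates(self):
        og, seqs = _toy_groups()
        small = screen_core_unique(og, ["I1", "I2"], ["O1"], seqs)
        large = screen_core_unique(og, ["I1", "I2"], ["O1", "O2"], seqs)
        assert {c.group_id for c in large} <= {c.group_id for c in small}

    def test_synthetic_panel_finds_exactly_the_planted_gene(self, small_panel):
        strains = sorted(small_panel.truth.labels)
        proteomes = {s: small_panel.proteome(s) for s in strains}
        rbh = {}
        for i, a in enumerate(strains):
            for b in strains[i + 1 :]:
                rbh[(a, b)] = protein_rbh(proteomes[a], proteomes[b])
        og = build_orthogroups(proteomes, rbh)
        seqs = {
            (s, g.gene_id): g.sequence
            for s, genes in small_panel.annotations.items()
            for g in genes
        }
        ingroup = [s for s, v in small_panel.truth.labels.items() if v == "ingroup"]
        outgroup = [s for s, v in small_panel.truth.labels.items() if v == "outgroup"]
        cands = screen_core_unique(og, sorted(ingroup), sorted(outgroup), seqs)
        planted = small_panel.truth.planted_gene_id
        assert [c.gene_id for c in cands] == [planted]


class TestPresenceBySearch:
    def test_verbatim_copy_is_present(self):
        rng = np.random.default_rng(3)
        gene = random_seq(rng, 600)
        g = GenomeRecord("g", [("c1", random_seq(rng, 3000) + gene + random_seq(rng, 3000))])
        call = presence_by_search(gene, g)
        assert call.present and call.hit.identity == 100.0

    def test_absent_from_unrelated_genome(self):
        rng = np.random.default_rng(4)
        gene = random_seq(rng, 600)
        g = GenomeRecord("g", [("c1", random_seq(rng, 20_000))])
        assert not presence_by_search(gene, g).present

    def test_diverged_copy_threshold_dependence(self):
        rng = np.random.default_rng(5)
        gene = random_seq(rng, 600)
        mutated = list(gene)
        for pos in rng.choice(600, size=60, replace=False):  # 10% substitutions
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        g = GenomeRecord(
            "g", [("c1", random_seq(rng, 2000) + "".join(mutated) + random_seq(rng, 2000))]
        )
        assert presence_by_search(gene, g, PresenceParams(min_identity=80.0)).present
        assert not presence_by_search(gene, g, PresenceParams(min_identity=95.0)).present


class TestConservationFilter:
    def test_planted_marker_survives_on_panel(self, small_panel):
        planted = small_panel.truth.planted_gene_id
        rep = next(
            g for g in small_panel.annotations["IN01"] if g.gene_id == planted
        )
        from strainsort.orthologs import DiagnosticCandidate

        cand = DiagnosticCandidate(
            group_id="OG0001",
            genome_id="IN01",
            gene_id=planted,
            sequence=rep.sequence,
            present_in=sorted(small_panel.truth.carriers),
            absent_from=[],
        )
        labels = {
            s: v == "ingroup" for s, v in small_panel.truth.labels.items()
        }
        kept = conservation_filter([cand], small_panel.genomes, labels)
        assert kept == [cand]

    def test_core_gene_dropped(self, small_panel):
        core = next(
            g for g in small_panel.annotations["IN01"] if g.gene_id == "core0001"
        )
        from strainsort.orthologs import DiagnosticCandidate

        cand = DiagnosticCandidate(
            group_id="OG0002",
            genome_id="IN01",
            gene_id="core0001",
            sequence=core.sequence,
            present_in=["IN01"],
            absent_from=[],
        )
        labels = {
            s: v == "ingroup" for s, v in small_panel.truth.labels.items()
        }
        # core genes are present in the out-group too, so the filter drops them
        assert conservation_filter([cand], small_panel.genomes, labels) == []
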