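"""Reciprocal-best-hit orthology, POG construction and pan-genome partitioning."""

import pytest

from taxg import (
    GeneRecord,
    POG,
    ReciprocalPair,
    all_vs_all_search,
    attach_partial_genes,
    assigned_fraction,
    build_pogs,
    category_frequencies,
    ortholog_matrix,
    partition,
    reciprocal_best_pairs,
    simulate_pangenome,
)
from taxg.config import PogConfig


def _gene(gene_id, genome_id, aa):
    return GeneRecord(
        gene_id=gene_id, genome_id=genome_id, contig_id="c1",
        start=1, end=3 * len(aa), strand="+", aa_seq=aa,
    )


PROT1 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"
PROT2 = "MSENLYFQGHHHHHHSSGLVPRGSHMASMTGGQQMGRGSEFELRRQACGRTRAPPPPPLRSGC"


class TestAllVsAllSearch:
    def test_identical_proteins_hit_both_directions(self):
        genomes = {"A": [_gene("a1", "A", PROT1)], "B": [_gene("b1", "B", PROT1)]}
        hits = all_vs_all_search(genomes)
        assert len(hits) == 2
        assert all(h.identity_fraction == 1.0 for h in hits)
        assert {(h.query_gene, h.subject_gene) for h in hits} == {("a1", "b1"), ("b1", "a1")}

    def test_unrelated_proteins_no_hit(self):
        genomes = {"A": [_gene("a1", "A", PROT1)], "B": [_gene("b1", "B", PROT2)]}
        assert all_vs_all_search(genomes) == []

    def test_missing_aa_seq_names_gene(self):
        bad = _gene("a1", "A", PROT1)
        bad.aa_seq = None
        with pytest.raises(ValueError, match="a1"):
            all_vs_all_search({"A": [bad], "B": [_gene("b1", "B", PROT1)]})

    def test_prefilter_matches_brute_force_oracle(self, small_pangenome):
        _, annotations, _ = small_pangenome
        fast = all_vs_all_search(annotations, prefilter=True)
        brute = all_vs_all_search(annotations, prefilter=False)
        fast_set = {(h.query_gene, h.subject_gene) for h in fast}
        brute_set = {(h.query_gene, h.subject_gene) for h in brute}
        assert fast_set <= brute_set

        def top_hits(hits):
            best = {}
            for h in hits:
                best.setdefault((h.query_gene, h.subject_genome), h.subject_gene)
            return best

        assert top_hits(fast) == top_hits(brute)


class TestReciprocalPairs:
    def _hit(self, q, s, qg, sg, score, identity=0.9):
        from taxg import SimilarityHit

        return SimilarityHit(q, s, qg, sg, identity, score, 1.0)

    def test_mutual_top_hits_paired(self):
        hits = [self._hit("a1", "b1", "A", "B", 100), self._hit("b1", "a1", "B", "A", 100)]
        (pair,) = reciprocal_best_pairs(hits)
        assert (pair.gene_a, pair.gene_b) == ("a1", "b1")

    def test_non_reciprocal_top_hit_excluded(self):
        hits = [
            self._hit("a1", "b1", "A", "B", 100),
            self._hit("b1", "a2", "B", "A", 120),
            self._hit("b1", "a1", "B", "A", 90),
            self._hit("a2", "b1", "A", "B", 120),
        ]
        pairs = reciprocal_best_pairs(hits)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a2", "b1")]

    def test_score_tie_breaks_lexicographically(self):
        # a1 hits b1 and b2 with equal score and identity: b1 wins the tie
        hits = [
            self._hit("a1", "b2", "A", "B", 100),
            self._hit("a1", "b1", "A", "B", 100),
            self._hit("b1", "a1", "B", "A", 100),
            self._hit("b2", "a1", "B", "A", 100),
        ]
        pairs = reciprocal_best_pairs(hits)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]


class TestBuildPogs:
    def test_transitive_linkage_single_component(self):
        pairs = [
            ReciprocalPair("a1", "b1", "A", "B"),
            ReciprocalPair("b1", "c1", "B", "C"),
        ]
        (pog,) = build_pogs(pairs)
        assert set(pog.members) == {"a1", "b1", "c1"}

    def test_disjoint_pairs_two_components(self):
        pairs = [
            ReciprocalPair("a1", "b1", "A", "B"),
            ReciprocalPair("a2", "b2", "A", "B"),
        ]
        pogs = build_pogs(pairs)
        assert [set(p.members) for p in pogs] == [{"a1", "b1"}, {"a2", "b2"}]

    def test_pair_only_merge_rule(self):
        pairs = [
            ReciprocalPair("a1", "b1", "A", "B"),
            ReciprocalPair("b1", "c1", "B", "C"),
        ]
        pogs = build_pogs(pairs, PogConfig(merge_rule="pair-only"))
        assert sorted(set(p.members) for p in pogs) == [{"a1", "b1"}, {"b1", "c1"}]

    def test_simulated_families_recovered(self, small_pangenome):
        _, annotations, truth = small_pangenome
        hits = all_vs_all_search(annotations)
        pogs = build_pogs(reciprocal_best_pairs(hits))
        pog_sets = [set(p.members) for p in pogs]
        recovered = sum(
            1 for members in truth.families.values() if set(members.values()) in pog_sets
        )
        assert recovered >= 0.95 * len(truth.families)


class TestAttachPartialGenes:
    def _setup(self):
        pog = POG("POG00001", {"a1": "A", "b1": "B"})
        index = {
            "a1": _gene("a1", "A", PROT1),
            "b1": _gene("b1", "B", PROT1[:70]),
        }
        return pog, index

    def test_partial_above_threshold_attached(self):
        pog, index = self._setup()
        fragment = _gene("c_part", "C", PROT1[:40])
        pogs, rest = attach_partial_genes([pog], [fragment], 0.95, index)
        assert "c_part" in pogs[0].members and rest == []

    def test_below_threshold_stays_unassigned(self):
        pog, index = self._setup()
        # 40-mer fragment with 3 substitutions: identity 37/40 = 0.925 < 0.95
        frag_seq = "AAA" + PROT1[3:40]
        fragment = _gene("c_part", "C", frag_seq)
        pogs, rest = attach_partial_genes([pog], [fragment], 0.95, index)
        assert rest == [fragment]

    def test_exactly_95_percent_is_inclusive(self):
        pog, index = self._setup()
        # 40-mer with 2 substitutions: identity 38/40 = 0.95 exactly
        frag_seq = "AA" + PROT1[2:40]
        fragment = _gene("c_part", "C", frag_seq)
        pogs, rest = attach_partial_genes([pog], [fragment], 0.95, index)
        assert "c_part" in pogs[0].members and rest == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            attach_partial_genes([], [], 0.0, {})


class TestPartition:
    def test_single_genome_all_strain_specific(self):
        genes = [_gene(f"a{i}", "A", PROT1) for i in range(4)]
        summary = partition([], {"A": genes})
        assert summary.core_pog_ids == []
        assert summary.per_genome.loc["A", "strain_specific"] == 4

    def test_pog_in_two_of_three_genomes_is_accessory(self):
        pog = POG("POG00001", {"a1": "A", "b1": "B"})
        genes = {
            "A": [_gene("a1", "A", PROT1)],
            "B": [_gene("b1", "B", PROT1)],
            "C": [_gene("c1", "C", PROT2)],
        }
        summary = partition([pog], genes)
        assert summary.core_pog_ids == []
        assert summary.per_genome.loc["A", "accessory"] == 1
        assert summary.per_genome.loc["C", "strain_specific"] == 1

    def test_gene_conservation_on_simulated_pangenome(self, small_pangenome):
        _, annotations, truth = small_pangenome
        hits = all_vs_all_search(annotations)
        pogs = build_pogs(reciprocal_best_pairs(hits))
        summary = partition(pogs, annotations)
        n_genes = sum(len(v) for v in annotations.values())
        assert summary.per_genome["total"].sum() == n_genes
        buckets = (
            summary.core_gene_ids
            | summary.accessory_gene_ids
            | summary.strain_specific_gene_ids
        )
        assert len(buckets) == n_genes
        # simulator truth: private genes are strain-specific, core families core
        private = {g for genes in truth.private.values() for g in genes}
        assert private <= summary.strain_specific_gene_ids

    def test_duplicate_pog_membership_rejected(self):
        pogs = [POG("P1", {"a1": "A", "b1": "B"}), POG("P2", {"a1": "A", "c1": "C"})]
        with pytest.raises(ValueError, match="more than one POG"):
            partition(pogs, {"A": [_gene("a1", "A", PROT1)]})


class TestCategories:
    def _summary(self):
        genes = {
            "A": [_gene("a1", "A", PROT1), _gene("a2", "A", PROT1)],
            "B": [_gene("b1", "B", PROT1)],
        }
        pog = POG("POG00001", {"a1": "A", "b1": "B"})
        return partition([pog], genes), genes

    def test_all_mapped_single_category(self):
        summary, genes = self._summary()
        freqs = category_frequencies(summary, genes, {"a1": "E", "a2": "E", "b1": "E"})
        assert freqs.loc["E", "pan"] == 3
        assert freqs.loc["E", "core"] == 2
        assert assigned_fraction(freqs, "pan") == 1.0

    def test_empty_mapping_all_unassigned(self):
        summary, genes = self._summary()
        freqs = category_frequencies(summary, genes, {})
        assert freqs.loc["unassigned", "pan"] == 3
        assert assigned_fraction(freqs, "pan") == 0.0

    def test_unknown_category_letter_errors(self):
        summary, genes = self._summary()
        with pytest.raises(ValueError, match="unknown COG category"):
            category_frequencies(summary, genes, {"a1": "z"})

    def test_planted_proportions_recovered(self, small_pangenome):
        _, annotations, _ = small_pangenome
        mapping = {}
        for genes in annotations.values():
            for i, g in enumerate(genes):
                mapping[g.gene_id] = "E" if i % 2 == 0 else "K"
        summary = partition([], annotations)
        freqs = category_frequencies(summary, annotations, mapping)
        expected_e = sum(
            (len(v) + 1) // 2 for v in annotations.values()
        )
        assert freqs.loc["E", "pan"] == expected_e


class TestOrthologMatrix:
    def test_shared_pogs_counted(self):
        pogs = [POG(f"P{i}", {f"a{i}": "A", f"b{i}": "B"}) for i in range(10)]
        mat = ortholog_matrix(pogs, ["A", "B"])
        assert mat.loc["A", "B"] == mat.loc["B", "A"] == 10
        assert mat.loc["A", "A"] == 10  # genes of A in any POG

    def test_symmetry_and_diagonal_dominance(self, small_pangenome):
        _, annotations, _ = small_pangenome
        hits = all_vs_all_search(annotations)
        pogs = build_pogs(reciprocal_best_pairs(hits))
        mat = ortholog_matrix(pogs, sorted(annotations))
        assert (mat.to_numpy() == mat.to_numpy().T).all()
        for g in mat.index:
            assert mat.loc[g, g] >= mat.loc[g].drop(g).max()
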