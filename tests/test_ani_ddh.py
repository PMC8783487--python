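"""Fragmentation, HSP search, ANI/dDDH estimation and distance matrices."""

import numpy as np
import pytest

from taxg import (
    DdhConfig,
    DdhMapping,
    GenomeAssembly,
    classify_species_boundary,
    ddh_distance,
    distance_matrix,
    find_hsps,
    fragment_genome,
    orthoani,
    random_genome,
    read_distance_matrix,
    simulate_genome_pair,
    write_distance_matrix,
)


class TestFragmentation:
    def test_floor_division_discards_trailing(self):
        g = random_genome(3_100, seed=1)
        fs = fragment_genome(g)
        assert len(fs) == 3
        assert fs.n_discarded_trailing == 40

    def test_too_short_contig_yields_empty_set(self):
        g = GenomeAssembly("tiny", [("c1", "A" * 1019)])
        assert len(fragment_genome(g)) == 0

    def test_two_contigs_with_recorded_origins(self):
        g = random_genome(4_080, n_contigs=2, seed=2)
        fs = fragment_genome(g)
        assert len(fs) == 4
        assert [(c, o) for _, _, c, o in fs.fragments] == [
            ("c1", 1), ("c1", 1021), ("c2", 1), ("c2", 1021),
        ]

    def test_high_n_fragments_dropped(self):
        g = random_genome(3_060, seed=3)
        cid, seq = g.contigs[0]
        seq = seq[:1020] + "N" * 300 + seq[1320:]
        fs = fragment_genome(GenomeAssembly("g", [(cid, seq)]))
        assert len(fs) == 2
        assert fs.n_discarded_ambiguous == 1


class TestFindHsps:
    def test_exact_substring_gives_perfect_hsp(self):
        g = random_genome(5_000, seed=4)
        query = g.contigs[0][1][1000:2020]
        (top, *_) = find_hsps(query, g, min_identity=0.9, min_len=500)
        assert top.identities == top.aligned_len == 1020
        assert top.subject_start == 1001 and top.subject_end == 2020

    def test_reverse_complement_hit_flagged_minus(self):
        from taxg import reverse_complement

        g = random_genome(5_000, seed=5)
        query = reverse_complement(g.contigs[0][1][1000:2020])
        (top, *_) = find_hsps(query, g, min_identity=0.9, min_len=500)
        assert top.strand == "-"
        assert top.identity_fraction == 1.0

    def test_planted_substitutions_counted(self):
        g = random_genome(5_000, seed=6)
        region = list(g.contigs[0][1][1000:2020])
        rng = np.random.default_rng(0)
        # plant 51 substitutions away from the ends so extension spans fully
        positions = 20 + rng.choice(980, size=51, replace=False)
        for pos in positions:
            region[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[region[pos]]
        (top, *_) = find_hsps("".join(region), g, min_identity=0.9, min_len=500)
        assert top.aligned_len == 1020
        assert top.identities == 1020 - 51

    def test_no_hits_returns_empty_list(self):
        g = random_genome(2_040, seed=7)
        assert find_hsps("A" * 300, g, min_identity=0.9, min_len=100) == []

    def test_gapped_alignment_via_indel(self):
        g = random_genome(5_000, seed=8)
        region = g.contigs[0][1][1000:2020]
        query = region[:500] + region[510:]  # 10-bp deletion
        (top, *_) = find_hsps(query, g, min_identity=0.9, min_len=500)
        assert top.aligned_len >= 1010
        assert top.identity_fraction > 0.98


class TestOrthoani:
    def test_self_comparison_is_exactly_100(self):
        g = random_genome(60_000, seed=9)
        res = orthoani(g, g)
        assert res.ani_percent == 100.0
        assert res.n_reciprocal_pairs == len(fragment_genome(g))

    def test_simulated_pair_recovers_divergence(self):
        a, b, expected = simulate_genome_pair(200_000, p=0.05, seed=1)
        res = orthoani(a, b)
        assert res.ani_percent == pytest.approx(expected, abs=0.3)

    def test_direction_symmetry(self):
        a, b, _ = simulate_genome_pair(100_000, p=0.05, seed=2)
        res = orthoani(a, b)
        assert abs(res.mean_ab - res.mean_ba) <= 1.0

    def test_too_few_fragments_errors(self):
        g = GenomeAssembly("short", [("c1", "ACGT" * 300)])
        with pytest.raises(ValueError, match=">= 2 fragments"):
            orthoani(g, g)

    def test_unrelated_genomes_flagged_undefined(self):
        a = random_genome(5_000, seed=10)
        b = random_genome(5_000, seed=11)
        res = orthoani(a, b)
        assert res.undefined and res.ani_percent is None


class TestDdh:
    def test_self_distance_is_exactly_zero(self):
        g = random_genome(50_000, seed=12)
        res = ddh_distance(g, g)
        assert res.d2 == 0.0
        assert res.ddh_percent == 100.0

    def test_distance_tracks_substitution_rate(self):
        a, b, _ = simulate_genome_pair(100_000, p=0.05, seed=3)
        res = ddh_distance(a, b)
        assert res.d2 == pytest.approx(0.05, abs=0.005)

    def test_no_homology_convention(self):
        a = random_genome(5_000, seed=13)
        b = random_genome(5_000, seed=14)
        res = ddh_distance(a, b)
        assert res.no_homology and res.d2 == 1.0

    def test_mapping_monotone_decreasing(self):
        m = DdhMapping()
        values = [m(d) for d in (0.0, 0.01, 0.0259, 0.05, 0.1, 0.3, 1.0)]
        assert values == sorted(values, reverse=True)
        assert m(0.0259) == pytest.approx(70.0, abs=0.5)

    def test_mapping_rejects_non_monotone_coefficients(self):
        with pytest.raises(ValueError):
            DdhMapping(a=1.0, b=-2.0)


class TestMonotonicity:
    def test_ani_decreases_and_d2_increases_with_divergence(self):
        anis, d2s = [], []
        for p in (0.01, 0.05, 0.10, 0.20):
            a, b, _ = simulate_genome_pair(60_000, p=p, seed=17)
            anis.append(orthoani(a, b).ani_percent)
            d2s.append(ddh_distance(a, b).d2)
        assert all(x > y for x, y in zip(anis, anis[1:]))
        assert all(x < y for x, y in zip(d2s, d2s[1:]))


class TestDistanceMatrix:
    def test_identical_genomes_zero_matrix(self):
        g = random_genome(30_000, seed=15)
        h = GenomeAssembly("copy", list(g.contigs))
        dm = distance_matrix([g, h], metric="ani_distance")
        assert np.allclose(dm.to_numpy(), 0.0)

    def test_matrix_matches_pairwise_calls(self):
        genomes = []
        base = random_genome(40_000, seed=16)
        from taxg import EvolutionParams, mutate_genome

        for i, p in enumerate((0.02, 0.08)):
            m, _ = mutate_genome(base, EvolutionParams(substitution_prob=p, seed=30 + i))
            m.genome_id = f"m{i}"
            genomes.append(m)
        genomes.append(base)
        dm = distance_matrix(genomes, metric="d2")
        for i in range(3):
            for j in range(i + 1, 3):
                expected = ddh_distance(genomes[i], genomes[j]).d2
                assert dm.iloc[i, j] == pytest.approx(expected, abs=1e-12)
                assert dm.iloc[j, i] == dm.iloc[i, j]
        assert np.allclose(np.diag(dm.to_numpy()), 0.0)

    def test_round_trip(self, tmp_path):
        g = random_genome(30_000, seed=18)
        h = GenomeAssembly("copy", list(g.contigs))
        dm = distance_matrix([g, h], metric="ani_distance")
        path = tmp_path / "dm.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert np.allclose(back.to_numpy(), dm.to_numpy())
        assert list(back.index) == list(dm.index)


class TestSpeciesBoundary:
    def test_requires_some_metric(self):
        with pytest.raises(ValueError):
            classify_species_boundary()

    @pytest.mark.parametrize(
        "ani,ddh,verdict",
        [
            (80.2, 24.4, "distinct"),
            (100.0, 100.0, "same"),
            (96.5, None, "same"),
            (None, 71.0, "same"),
            (94.9, 69.9, "distinct"),
        ],
    )
    def test_thresholds(self, ani, ddh, verdict):
        assert classify_species_boundary(ani_percent=ani, ddh_percent=ddh) == verdict
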