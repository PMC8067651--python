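"""Reference-database construction: normalization, clustering, averaging, merging."""

import random

import pytest

from funred import (
    GenomeRecord,
    ReferenceDatabase,
    build_cluster_profile,
    build_reference_database,
    cluster_sequences,
    merge_databases,
    normalize_profile,
)
from oracles import brute_association, brute_cluster


class TestNormalizeProfile:
    @pytest.mark.parametrize(
        "counts, n_ssu, expected",
        [
            ({"K00001": 4, "K00002": 2}, 2, {"K00001": 2.0, "K00002": 1.0}),
            ({"K00001": 3}, 1, {"K00001": 3.0}),
            ({}, 5, {}),
        ],
    )
    def test_division_by_copy_number(self, counts, n_ssu, expected):
        assert normalize_profile(counts, n_ssu) == expected

    def test_genome_without_16s_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile({"K00001": 1}, 0)


def random_sequences(n, length, seed, n_families=None):
    """n sequences drawn from a few divergent families with light mutation."""
    rng = random.Random(seed)
    n_families = n_families or max(2, n // 3)
    families = [
        "".join(rng.choice("ACGT") for _ in range(length)) for _ in range(n_families)
    ]
    out = []
    for i in range(n):
        base = list(rng.choice(families))
        for j in rng.sample(range(length), rng.randint(0, length // 20)):
            base[j] = rng.choice([b for b in "ACGT" if b != base[j]])
        out.append((f"s{i:02d}", "".join(base)))
    return out


class TestClusterSequences:
    def test_identical_pair_joins_one_cluster(self):
        seqs = [("a|1", "ACGT" * 50), ("b|1", "ACGT" * 50)]
        clusters = cluster_sequences(seqs, 0.99)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_seq_ids) == ["a|1", "b|1"]

    def test_divergent_pair_stays_separate(self):
        a = "ACGT" * 50
        b = list(a)
        for i in range(0, 40, 4):  # 10 substitutions -> 95% identity
            b[i] = "T" if b[i] != "T" else "G"
        clusters = cluster_sequences([("a|1", a), ("b|1", "".join(b))], 0.99)
        assert len(clusters) == 2

    def test_five_identical_pairs_give_five_clusters(self):
        """5 pairs of duplicates at threshold 1.0; brute-force partition agrees."""
        rng = random.Random(3)
        pairs = []
        for k in range(5):
            seq = "".join(rng.choice("ACGT") for _ in range(200))
            pairs += [(f"p{k}a", seq), (f"p{k}b", seq)]
        clusters = cluster_sequences(pairs, 1.0)
        assert len(clusters) == 5
        assert all(len(c.member_seq_ids) == 2 for c in clusters)
        oracle = brute_cluster(pairs, 1.0)
        assert sorted(map(sorted, oracle)) == sorted(sorted(c.member_seq_ids) for c in clusters)

    def test_empty_input_gives_empty_list(self):
        assert cluster_sequences([], 0.99) == []

    def test_longest_sequence_is_centroid(self):
        long = "ACGT" * 60
        short = long[:200]
        clusters = cluster_sequences([("short", short), ("long", long)], 0.97)
        assert clusters[0].centroid_id == "long"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("threshold", [0.97, 0.99, 1.0])
    def test_matches_brute_force_oracle(self, seed, threshold):
        """Greedy clustering equals an independent reimplementation on <=30 sequences."""
        seqs = random_sequences(24, 150, seed)
        ours = [sorted(c.member_seq_ids) for c in cluster_sequences(seqs, threshold)]
        oracle = [sorted(m) for m in brute_cluster(seqs, threshold)]
        assert ours == oracle

    def test_cluster_count_monotone_in_threshold(self):
        seqs = random_sequences(20, 150, 5)
        n99 = len(cluster_sequences(seqs, 0.99))
        n100 = len(cluster_sequences(seqs, 1.0))
        assert n100 >= n99

    def test_copy_conservation(self, three_genomes):
        """Each genome's copies, summed over clusters, equal its 16S copy number."""
        seqs = [
            (f"{g.genome_id}|{i}", s)
            for g in three_genomes
            for i, s in enumerate(g.ssu_sequences, start=1)
        ]
        clusters = cluster_sequences(seqs, 0.99)
        copies: dict[str, int] = {}
        for cl in clusters:
            for gid, c in cl.members:
                copies[gid] = copies.get(gid, 0) + c
        assert copies == {g.genome_id: g.n_ssu for g in three_genomes}


class TestBuildClusterProfile:
    def test_singleton(self):
        abundance, presence = build_cluster_profile([({"K1": 2.0}, 1)])
        assert abundance == {"K1": 2.0}
        assert presence == {"K1": 1.0}

    def test_multiplicity_scaled_mean(self):
        members = [({"K1": 2.0}, 1), ({"K1": 1.0, "K2": 1.0}, 2)]
        abundance, presence = build_cluster_profile(members)
        assert abundance == {"K1": pytest.approx(2.0), "K2": pytest.approx(1.0)}
        assert presence == {"K1": 1.0, "K2": 0.5}

    def test_weighted_mean_mode(self):
        members = [({"K1": 2.0}, 1), ({"K1": 1.0, "K2": 1.0}, 2)]
        abundance, _ = build_cluster_profile(members, mode="weighted_mean")
        assert abundance == {"K1": pytest.approx(4 / 3), "K2": pytest.approx(2 / 3)}

    def test_absent_ko_dropped_from_abundance(self):
        members = [({"K1": 1.0, "K9": 0.0}, 1)] * 3
        abundance, presence = build_cluster_profile(members)
        assert "K9" not in abundance
        assert presence["K9"] == 0.0

    def test_zero_members_rejected(self):
        with pytest.raises(ValueError):
            build_cluster_profile([])


class TestBuildReferenceDatabase:
    def test_dissimilar_genomes_make_singleton_references(self, three_genomes):
        db = build_reference_database(three_genomes, threshold=0.99)
        assert len(db.ref_sequences) == 3

    def test_identical_16s_collapses_to_one_reference(self):
        seq = "ACGT" * 100
        genomes = [
            GenomeRecord("gA", [seq], {"K1": 2}),
            GenomeRecord("gB", [seq], {"K1": 4, "K2": 2}),
        ]
        db = build_reference_database(genomes, threshold=0.99)
        assert len(db.ref_sequences) == 1
        rid = db.reference_ids[0]
        # scaled mean over 2 genomes, one copy each
        assert db.association_matrix.at[rid, "K1"] == pytest.approx((2 + 4) / 2)
        assert db.association_matrix.at[rid, "K2"] == pytest.approx(1.0)
        assert db.presence_fraction.at[rid, "K1"] == 1.0
        assert db.presence_fraction.at[rid, "K2"] == 0.5

    def test_matches_brute_force_recomputation(self, small_world):
        """Every association and presence cell equals a first-principles recount."""
        db = build_reference_database(small_world.genomes, threshold=0.99)
        abundance, presence = brute_association(small_world.genomes, 0.99)
        assert set(abundance) == set(db.reference_ids)
        for rid in db.reference_ids:
            for ko in db.association_matrix.columns:
                assert db.association_matrix.at[rid, ko] == pytest.approx(
                    abundance[rid].get(ko, 0.0)
                ), (rid, ko)
                assert db.presence_fraction.at[rid, ko] == pytest.approx(
                    presence[rid].get(ko, 0.0)
                ), (rid, ko)

    def test_presence_fraction_is_one_iff_all_members_have_ko(self, small_world):
        db = build_reference_database(small_world.genomes, threshold=0.99)
        values = db.presence_fraction.values
        assert values.min() >= 0.0 and values.max() <= 1.0
        # fraction 1 exactly for KOs carried by every member genome
        presence = small_world.function_presence
        ref = db.reference_ids[0]
        member_gids = [gid for gid, _ in next(
            cl.members for cl in cluster_sequences(
                [(f"{g.genome_id}|{i}", s) for g in small_world.genomes
                 for i, s in enumerate(g.ssu_sequences, start=1)], 0.99)
            if cl.centroid_id == ref
        )]
        for ko in db.presence_fraction.columns:
            expected = all(presence.at[gid, ko] for gid in member_gids)
            assert (db.presence_fraction.at[ref, ko] == 1.0) == expected

    def test_no_clustering_mode_keeps_every_sequence(self, three_genomes):
        db = build_reference_database(three_genomes, threshold=0.99, cluster=False)
        assert len(db.ref_sequences) == sum(g.n_ssu for g in three_genomes)

    def test_duplicate_genome_ids_rejected(self, three_genomes):
        with pytest.raises(ValueError, match="duplicate"):
            build_reference_database(three_genomes + [three_genomes[0]])

    def test_genome_without_16s_excluded_with_warning(self, three_genomes, caplog):
        bare = GenomeRecord("gEmpty", [], {"K1": 1})
        db = build_reference_database(three_genomes + [bare], threshold=0.99)
        assert len(db.ref_sequences) == 3
        assert any("gEmpty" in rec.message for rec in caplog.records)

    def test_roundtrip_save_load(self, three_genomes, tmp_path):
        db = build_reference_database(
            three_genomes, threshold=0.99, pathway_map={"K00001": {"path1"}}
        )
        db.save(tmp_path / "db")
        loaded = ReferenceDatabase.load(tmp_path / "db")
        assert loaded.threshold == db.threshold
        assert loaded.ref_sequences == db.ref_sequences
        assert loaded.pathway_map == db.pathway_map
        assert (loaded.association_matrix - db.association_matrix).abs().values.max() < 1e-5
        assert sorted(l.taxon.label for l in loaded.tree.leaf_node_iter()) == sorted(
            db.ref_sequences
        )


class TestMergeDatabases:
    def test_disjoint_union_with_provenance(self, three_genomes, small_world):
        db_a = build_reference_database(small_world.genomes[:5], threshold=0.99)
        db_b = build_reference_database(three_genomes, threshold=0.99, provenance="user")
        merged = merge_databases(db_a, db_b)
        assert len(merged.reference_ids) == len(db_a.ref_sequences) + len(db_b.ref_sequences)
        assert all(
            rid.startswith("user:") == (merged.resolve(rid)[0] is merged.user)
            for rid in merged.reference_ids
        )

    def test_flatten_preserves_profiles(self, three_genomes, small_world):
        db_a = build_reference_database(small_world.genomes[:4], threshold=0.99)
        db_b = build_reference_database(three_genomes, threshold=0.99)
        flat = merge_databases(db_a, db_b).to_reference_database()
        for rid in db_a.reference_ids:
            for ko in db_a.association_matrix.columns:
                assert flat.association_matrix.at[rid, ko] == pytest.approx(
                    db_a.association_matrix.at[rid, ko]
                )
        leaves = {l.taxon.label for l in flat.tree.leaf_node_iter()}
        assert leaves == set(flat.ref_sequences)
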