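"""Merging, insert extraction, greedy clustering, and hit calling."""

import numpy as np
import pytest

from randgene import (
    LibraryConfig,
    SelectionConfig,
    VariantTable,
    call_functional,
    cluster_sequences,
    enrichment_table,
    extract_insert,
    generate_library,
    merge_pairs,
    process_read_set,
    sequence_identity,
    simulate_selection,
)
from randgene.amplicon_pipeline import Cluster, _identity_at_least
from randgene.library_synth import reverse_complement, sequence_experiment_post


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestMergePairs:
    def test_exact_overlap_reconstructs_fragment(self, rng):
        frag = random_seq(rng, 156)
        r1, r2 = frag[:98], reverse_complement(frag[-98:])  # 40-nt overlap
        assert merge_pairs(r1, r2, min_overlap=20) == frag

    def test_disjoint_reads_fail(self, rng):
        r1 = random_seq(rng, 50)
        r2 = random_seq(rng, 50)
        assert merge_pairs(r1, r2, min_overlap=30) is None

    def test_mismatch_resolved_by_quality(self, rng):
        frag = random_seq(rng, 100)
        r1 = frag[:70]
        rc_region = frag[-70:]
        # put one error into read2 inside the 40-nt overlap
        err_pos = 40  # position within rc_region; overlap spans rc_region[:40]
        rc_err = mutate(rc_region, [10], rng)
        r2 = reverse_complement(rc_err)
        q_low = [10] * 70
        q_high = [40] * 70
        # read1 higher quality -> read1 base wins, fragment restored
        assert merge_pairs(r1, r2, q_high, q_low) == frag
        # read2 higher quality -> the error wins at that position
        merged = merge_pairs(r1, r2, q_low, q_high)
        assert merged == frag[:30] + rc_err

    def test_mismatch_fraction_gate(self, rng):
        frag = random_seq(rng, 100)
        r1 = frag[:70]
        rc_region = mutate(frag[-70:], list(range(0, 40, 4)), rng)  # 10/40 errors
        r2 = reverse_complement(rc_region)
        assert merge_pairs(r1, r2, max_mismatch_fraction=0.1) is None


class TestExtractInsert:
    FLANK5, FLANK3 = "GGAGGTACTAGT", "GGATCCAAACTC"

    def test_exact_flanks(self, rng):
        insert = random_seq(rng, 156)
        read = self.FLANK5 + insert + self.FLANK3
        assert extract_insert(read, self.FLANK5, self.FLANK3) == insert

    def test_one_substitution_in_flank_tolerated(self, rng):
        insert = random_seq(rng, 156)
        flank5_err = mutate(self.FLANK5, [4], rng)
        read = flank5_err + insert + self.FLANK3
        assert extract_insert(read, self.FLANK5, self.FLANK3,
                              max_flank_mismatches=2) == insert

    def test_too_many_flank_mismatches_drops_read(self, rng):
        insert = random_seq(rng, 50)
        bad5 = mutate(self.FLANK5, [0, 3, 6, 9], rng)
        read = bad5 + insert + self.FLANK3
        assert extract_insert(read, self.FLANK5, self.FLANK3,
                              max_flank_mismatches=2) is None

    def test_adjacent_flanks_yield_nothing(self):
        read = self.FLANK5 + self.FLANK3
        assert extract_insert(read, self.FLANK5, self.FLANK3) is None


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert sequence_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_substitutions_only(self, rng):
        s = random_seq(rng, 150)
        t = mutate(s, [3, 50, 100], rng)
        assert sequence_identity(s, t) == pytest.approx(147 / 150)

    def test_decision_helper_agrees_with_full_alignment(self, rng):
        """Fast accept/reject paths never change the threshold decision."""
        for _ in range(60):
            s = random_seq(rng, 120)
            n_mut = int(rng.integers(0, 12))
            t = mutate(s, list(rng.choice(120, size=n_mut, replace=False)), rng)
            if rng.random() < 0.3:  # sprinkle an indel
                p = int(rng.integers(0, len(t)))
                t = t[:p] + t[p + 1:]
            for thr in (0.9, 0.95, 0.99):
                assert _identity_at_least(s, t, thr) == (
                    sequence_identity(s, t) >= thr
                )


class TestClustering:
    def test_duplicates_collapse_to_one_cluster(self):
        table = VariantTable(entries=[("ACGT" * 30, 7)])
        clusters = cluster_sequences(table)
        assert len(clusters) == 1
        assert clusters[0].total_count == 7

    def test_ten_differences_split_two_clusters(self, rng):
        s = random_seq(rng, 150)
        t = mutate(s, list(range(5, 150, 15)), rng)  # 10 scattered substitutions
        assert sequence_identity(s, t) == pytest.approx(140 / 150)
        table = VariantTable(entries=[(s, 5), (t, 3)])
        assert len(cluster_sequences(table, 0.95)) == 2

    def test_seven_differences_join_highest_count_centroid(self, rng):
        s = random_seq(rng, 150)
        t = mutate(s, list(range(5, 150, 22)), rng)  # 7 scattered substitutions
        table = VariantTable(entries=[(t, 9), (s, 5)])
        clusters = cluster_sequences(table, 0.95)
        assert len(clusters) == 1
        assert clusters[0].centroid == t  # higher count seeds the cluster

    def test_count_conservation(self, rng):
        seqs = {}
        for _ in range(30):
            base = random_seq(rng, 120)
            seqs[base] = int(rng.integers(1, 50))
            child = mutate(base, [int(rng.integers(0, 120))], rng)
            if child not in seqs:
                seqs[child] = 1
        table = VariantTable.from_counts(seqs)
        clusters = cluster_sequences(table)
        assert sum(c.total_count for c in clusters) == table.total_reads

    def test_greedy_contract_against_brute_force(self, rng):
        """Oracle: replay the greedy rule with the raw aligner on 50 seqs."""
        entries = {}
        for _ in range(12):
            base = random_seq(rng, 90)
            entries[base] = int(rng.integers(5, 100))
            for _ in range(3):
                n = int(rng.integers(1, 6))
                child = mutate(base, list(rng.choice(90, n, replace=False)), rng)
                entries.setdefault(child, int(rng.integers(1, 4)))
        table = VariantTable.from_counts(dict(list(entries.items())[:50]))
        clusters = cluster_sequences(table, 0.95)
        # contract: every member within threshold of its centroid
        for c in clusters:
            for seq, _ in c.members:
                assert sequence_identity(seq, c.centroid) >= 0.95
        # oracle replay using only the exact aligner
        ordered = sorted(table.entries, key=lambda e: (-e[1], e[0]))
        oracle = []
        for seq, count in ordered:
            for oc in oracle:
                if sequence_identity(seq, oc[0]) >= 0.95:
                    oc[1].append(seq)
                    break
            else:
                oracle.append([seq, [seq]])
        assert [c.centroid for c in clusters] == [oc[0] for oc in oracle]
        assert [[m for m, _ in c.members] for c in clusters] == [
            oc[1] for oc in oracle
        ]


class TestCallFunctional:
    def _clusters(self, counts):
        return [
            Cluster(centroid=f"SEQ{i}", members=[(f"SEQ{i}", c)])
            for i, c in enumerate(counts)
        ]

    def test_threshold_is_inclusive_at_146_reads(self):
        """At 2.92M reads, 5e-5 corresponds to exactly 146 reads."""
        total = 2_920_000
        call = call_functional(self._clusters([146, 145]), total, 5e-5)
        assert call.min_reads == 146
        assert [h["count"] for h in call.hits] == [146]
        assert call.hits[0]["frequency"] == pytest.approx(5e-5)

    def test_impossible_threshold_yields_no_hits(self):
        call = call_functional(self._clusters([10, 5]), 15, 1.0)
        assert call.hits == []

    def test_empty_table(self):
        call = call_functional([], 0)
        assert call.hits == [] and call.min_reads == 0

    def test_raising_threshold_never_adds_hits(self):
        clusters = self._clusters([400, 150, 60, 9, 1])
        total = 1_000_000
        prev = None
        for thr in (1e-6, 5e-6, 5e-5, 2e-4, 1e-3):
            hits = call_functional(clusters, total, thr).hit_centroids
            if prev is not None:
                assert hits <= prev
            prev = hits

    def test_adding_reads_to_a_hit_keeps_it(self):
        total = 100_000
        base = call_functional(self._clusters([10, 3]), total, 1e-4)
        grown = call_functional(self._clusters([25, 3]), total + 15, 1e-4)
        assert base.hit_centroids <= grown.hit_centroids


class TestEnrichment:
    def test_identical_populations_have_unit_fold_change(self, rng):
        clusters = [
            Cluster(centroid=random_seq(rng, 60), members=[("x", 10)])
            for _ in range(3)
        ]
        df = enrichment_table(clusters, clusters, 30, 30)
        assert np.allclose(df["fold_change"], 1.0)
        assert not df["de_novo"].any()

    def test_absent_in_pre_is_flagged_de_novo(self, rng):
        pre = [Cluster(centroid=random_seq(rng, 60), members=[("x", 10)])]
        novel = Cluster(centroid=random_seq(rng, 60), members=[("y", 5)])
        df = enrichment_table(pre, pre + [novel], 10, 15)
        assert df.loc[df["centroid"] == novel.centroid, "de_novo"].item()

    def test_planted_variants_enrich_in_simulation(self, nnb):
        cfg = LibraryConfig(scheme=nnb, n_variants=150, seed=30)
        lib = generate_library(cfg)
        sel = SelectionConfig(
            p_escape=1e-3, fraction_functional=0.05, bottleneck=50_000
        )
        exp = simulate_selection(lib, sel, seed=31)
        pre_cl = cluster_sequences(exp.pre)
        post_cl = cluster_sequences(exp.post)
        df = enrichment_table(
            pre_cl, post_cl, exp.pre.total_reads, exp.post.total_reads
        )
        functional = {v.insert for v in lib.variants if v.variant_id in exp.truth}
        planted = df[df["centroid"].isin(functional)]
        assert planted["fold_change"].median() > 1


class TestEndToEnd:
    def test_error_free_simulation_merges_everything(self, nnb):
        cfg = LibraryConfig(scheme=nnb, n_variants=40, seed=32)
        lib = generate_library(cfg)
        exp = simulate_selection(lib, SelectionConfig(bottleneck=20_000), seed=33)
        rs = sequence_experiment_post(exp, depth=5_000,
                                      substitution_rate=0.0, seed=34)
        table, clusters, hits, summary = process_read_set(
            rs, cfg.flank5, cfg.flank3
        )
        assert summary.merge_failures == 0
        assert summary.flank_failures == 0
        assert summary.merged == 5_000
        post_inserts = {s for s, _ in exp.post.entries}
        assert {s for s, _ in table.entries} <= post_inserts

    def test_bulk_merge_consensus_matches_scalar_rule(self, nnb):
        """The vectorized pipeline merge equals merge_pairs read by read."""
        cfg = LibraryConfig(scheme=nnb, n_variants=10, seed=35)
        lib = generate_library(cfg)
        amps = [lib.amplicon(v) for v in lib.variants]
        from randgene import sequence_reads

        rs = sequence_reads(amps, lib.abundances, depth=400,
                            substitution_rate=5e-3, seed=36)
        scalar_counts = {}
        for r1, r2, count in rs.pairs:
            merged = merge_pairs(r1, r2, min_overlap=20)
            if merged is None:
                continue
            insert = extract_insert(merged, cfg.flank5, cfg.flank3)
            if insert is None:
                continue
            scalar_counts[insert] = scalar_counts.get(insert, 0) + count
        table, _, _, _ = process_read_set(rs, cfg.flank5, cfg.flank3)
        assert dict(table.entries) == scalar_counts
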