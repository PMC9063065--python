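import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import random_cds
from oracles import global_alignment_score_bruteforce, rbh_bruteforce, triangles_bruteforce
from wgdkit import seqio
from wgdkit.homology import (
    GAP_EXTEND,
    GAP_OPEN,
    DuplicatePair,
    OrthologCluster,
    align_pair,
    build_111_clusters,
    find_duplicate_pairs,
    pairs_to_frame,
    rbh_from_scores,
    read_hits_tabular,
    reciprocal_best_hits,
)
from wgdkit.seqio import ProteinRecord

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_prot(rng, n, id="p"):
    return ProteinRecord(id, "".join(rng.choice(list(AA), size=n)))


def mutated(rng, prot, keep, id="q"):
    aa = [c if rng.random() < keep else rng.choice(list(AA)) for c in prot.aa]
    return ProteinRecord(id, "".join(aa))


class TestAlignPair:
    def test_identical_local_full_metrics(self, rng):
        p = rand_prot(rng, 100, "a")
        q = ProteinRecord("b", p.aa)
        hit, (g1, g2) = align_pair(p, q, mode="local")
        assert hit.identity_pct == hit.similarity_pct == 100.0
        assert hit.coverage_q_pct == hit.coverage_s_pct == 100.0
        assert g1 == g2 == p.aa

    def test_global_score_is_blosum_diagonal_sum(self):
        hit, _ = align_pair(ProteinRecord("a", "MKV"), ProteinRecord("b", "MKV"))
        assert hit.score == B62["M", "M"] + B62["K", "K"] + B62["V", "V"]

    def test_score_symmetric(self, rng):
        for _ in range(5):
            p, q = rand_prot(rng, 40, "a"), rand_prot(rng, 35, "b")
            h1, _ = align_pair(p, q)
            h2, _ = align_pair(q, p)
            assert h1.score == h2.score

    def test_matches_bruteforce_enumeration_on_tiny_inputs(self, rng):
        # exhaustive enumeration of all monotone alignments, <= 6 residues
        for _ in range(8):
            p = rand_prot(rng, int(rng.integers(2, 6)), "a")
            q = rand_prot(rng, int(rng.integers(2, 6)), "b")
            expected = global_alignment_score_bruteforce(
                p.aa, q.aa, B62, GAP_OPEN, GAP_EXTEND
            )
            hit, _ = align_pair(p, q, mode="global")
            assert hit.score == pytest.approx(expected)

    def test_invalid_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="mode"):
            align_pair(rand_prot(rng, 5, "a"), rand_prot(rng, 5, "b"), mode="fuzzy")


class TestFindDuplicatePairs:
    def test_identical_pair_retained(self, rng):
        p = rand_prot(rng, 100, "a")
        pairs = find_duplicate_pairs([p, ProteinRecord("b", p.aa)])
        assert len(pairs) == 1
        assert pairs[0].key == ("a", "b")

    def test_short_identical_pair_dropped_by_length_filter(self, rng):
        p = rand_prot(rng, 25, "a")
        assert find_duplicate_pairs([p, ProteinRecord("b", p.aa)]) == []

    def test_constructed_trio_filters_on_similarity(self, rng):
        a = rand_prot(rng, 120, "a")
        b = mutated(rng, a, keep=0.95, id="b")   # ~95% identity, passes
        c = mutated(rng, a, keep=0.45, id="c")   # far below 70% positives
        pairs = find_duplicate_pairs([a, b, c])
        assert {p.key for p in pairs} == {("a", "b")}

    def test_threshold_monotonicity(self, rng):
        prots = [rand_prot(rng, 60, "seed")]
        for i in range(5):
            prots.append(mutated(rng, prots[0], keep=0.6 + 0.08 * i, id=f"m{i}"))
        base = {p.key for p in find_duplicate_pairs(prots, prefilter="none")}
        for msim, mcov, mlen in [(80, 80, 30), (70, 90, 30), (70, 80, 50)]:
            tighter = {
                p.key
                for p in find_duplicate_pairs(
                    prots, min_similarity=msim, min_coverage=mcov, min_len=mlen,
                    prefilter="none",
                )
            }
            assert tighter <= base

    def test_prefilter_agrees_with_exhaustive(self, rng):
        family = [rand_prot(rng, 80, "f0")]
        for i in range(1, 12):
            family.append(mutated(rng, family[0], keep=0.88, id=f"f{i}"))
        family += [rand_prot(rng, 80, f"r{i}") for i in range(8)]
        exact = find_duplicate_pairs(family, prefilter="none")
        kmer = find_duplicate_pairs(family, prefilter="kmer")
        assert [p.key for p in exact] == [p.key for p in kmer]

    def test_empty_proteome_warns(self, rng):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert find_duplicate_pairs([rand_prot(rng, 40, "a")]) == []

    def test_canonical_order_enforced(self):
        with pytest.raises(ValueError, match="canonical"):
            DuplicatePair("b", "a", 1.0, 90.0, 95.0, 90.0, 90.0)


class TestRBH:
    def test_single_gene_each_side(self, rng):
        p, q = rand_prot(rng, 40, "a"), rand_prot(rng, 40, "b")
        assert reciprocal_best_hits([p], [q]) == {("a", "b")}

    def test_asymmetric_best_hit_excluded(self):
        # a's best is b, but b's best is a2
        scores = np.array([[10.0, 5.0], [20.0, 1.0]])  # rows a, a2; cols b, c
        got = rbh_from_scores(scores, ["a", "a2"], ["b", "c"])
        assert ("a", "b") not in got
        assert got == {("a2", "b")}

    def test_ties_disqualify(self):
        scores = np.array([[7.0, 7.0]])
        assert rbh_from_scores(scores, ["a"], ["b", "c"]) == set()

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 8, size=(10, 10)).astype(float)
            ids1 = [f"x{i}" for i in range(10)]
            ids2 = [f"y{i}" for i in range(10)]
            assert rbh_from_scores(scores, ids1, ids2) == rbh_bruteforce(
                scores, ids1, ids2
            )

    def test_partial_matching_invariant(self, rng):
        scores = rng.random((15, 12))
        got = rbh_from_scores(scores, [f"x{i}" for i in range(15)],
                              [f"y{i}" for i in range(12)])
        assert len({a for a, _ in got}) == len(got)
        assert len({b for _, b in got}) == len(got)

    def test_empty_proteome_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            reciprocal_best_hits([], [rand_prot(rng, 30, "b")])


class TestClusters111:
    def test_consistent_triangle(self):
        rbh = {("s1", "s2"): {("a", "b")}, ("s1", "s3"): {("a", "c")},
               ("s2", "s3"): {("b", "c")}}
        got = build_111_clusters(rbh, ("s1", "s2", "s3"))
        assert len(got) == 1
        assert got[0].member_ids == {"s1": "a", "s2": "b", "s3": "c"}

    def test_missing_edge_closes_nothing(self):
        rbh = {("s1", "s2"): {("a", "b")}, ("s1", "s3"): {("a", "c")},
               ("s2", "s3"): set()}
        assert build_111_clusters(rbh, ("s1", "s2", "s3")) == []

    def test_reversed_orientation_accepted(self):
        rbh = {("s2", "s1"): {("b", "a")}, ("s1", "s3"): {("a", "c")},
               ("s3", "s2"): {("c", "b")}}
        assert len(build_111_clusters(rbh, ("s1", "s2", "s3"))) == 1

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            g1 = [f"a{i}" for i in range(6)]
            g2 = [f"b{i}" for i in range(6)]
            g3 = [f"c{i}" for i in range(6)]
            # random partial matchings
            def matching(u, v):
                perm = rng.permutation(len(v))
                return {(u[i], v[perm[i]]) for i in range(len(u)) if rng.random() < 0.6}
            r12, r13, r23 = matching(g1, g2), matching(g1, g3), matching(g2, g3)
            got = build_111_clusters(
                {("s1", "s2"): r12, ("s1", "s3"): r13, ("s2", "s3"): r23},
                ("s1", "s2", "s3"),
            )
            expected = triangles_bruteforce(r12, r13, r23)
            assert {tuple(c.member_ids[s] for s in ("s1", "s2", "s3")) for c in got} == expected

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="not distinct"):
            build_111_clusters({}, ("s1", "s1", "s3"))
        with pytest.raises(ValueError, match="missing RBH"):
            build_111_clusters({("s1", "s2"): set()}, ("s1", "s2", "s3"))


class TestTabular:
    def test_pairs_frame_and_hits_import(self, tmp_path, rng):
        p = rand_prot(rng, 100, "a")
        pairs = find_duplicate_pairs([p, ProteinRecord("b", p.aa)])
        frame = pairs_to_frame(pairs)
        assert list(frame.columns[:2]) == ["id_a", "id_b"]
        hits = tmp_path / "hits.tsv"
        hits.write_text("q\ts\t98.5\t100\t1\t0\t1\t100\t1\t100\t1e-50\t180\n")
        df = read_hits_tabular(hits)
        assert df.loc[0, "pident"] == 98.5
        bad = tmp_path / "bad.tsv"
        bad.write_text("q\ts\t98.5\n")
        with pytest.raises(ValueError, match="12"):
            read_hits_tabular(bad)
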