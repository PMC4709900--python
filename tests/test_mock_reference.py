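"""Stage 2: pair merging, stitching, identity, clustering, mock reference."""

import numpy as np
import pytest

from gbsnp.dna import revcomp
from gbsnp.mock_reference import (
    Centroid,
    MockReference,
    build_mock_reference,
    greedy_cluster,
    merge_and_stitch,
    merge_pair,
    pairwise_identity,
    stitch_pair,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


def _seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _reads_from_fragment(frag, read_len=150):
    r1 = frag[:read_len]
    r2 = revcomp(frag[-read_len:]) if len(frag) >= read_len else revcomp(frag)
    return (r1, "I" * len(r1)), (r2, "I" * len(r2))


def semiglobal_distance(query, target):
    """O(nm) DP oracle: edit distance of query aligned within target (free
    terminal gaps on the target)."""
    n, m = len(query), len(target)
    prev = [0] * (m + 1)  # free start gap in target
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (query[i - 1] != target[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)  # free end gap in target


class TestMergePair:
    def test_fragment_reconstructed_exactly(self):
        frag = _seq(_rng(1), 250)
        r1, r2 = _reads_from_fragment(frag)
        status, merged = merge_pair(r1, r2)
        assert status == "merged"
        assert merged[0] == frag

    def test_no_overlap_unmerged(self):
        frag = _seq(_rng(2), 350)
        r1, r2 = _reads_from_fragment(frag)
        assert merge_pair(r1, r2)[0] == "unmerged"

    def test_nine_bp_overlap_below_minimum(self):
        frag = _seq(_rng(3), 2 * 150 - 9)
        r1, r2 = _reads_from_fragment(frag)
        assert merge_pair(r1, r2)[0] == "unmerged"

    def test_ten_bp_overlap_meets_minimum(self):
        frag = _seq(_rng(4), 2 * 150 - 10)
        r1, r2 = _reads_from_fragment(frag)
        status, merged = merge_pair(r1, r2)
        assert status == "merged" and merged[0] == frag

    def test_mismatch_resolved_toward_higher_quality(self):
        frag = _seq(_rng(5), 200)
        (s1, q1), (s2, q2) = _reads_from_fragment(frag)
        # corrupt one R1 base inside the overlap (positions 50..149 of R1)
        pos = 100
        s1_bad = s1[:pos] + ("A" if s1[pos] != "A" else "C") + s1[pos + 1 :]
        q1_low = q1[:pos] + "#" + q1[pos + 1 :]  # Phred 2 at the error
        status, merged = merge_pair((s1_bad, q1_low), (s2, q2))
        assert status == "merged"
        assert merged[0] == frag  # R2's higher-quality base wins

    def test_short_product_discarded(self):
        frag = _seq(_rng(6), 20)
        r1 = (frag, "I" * 20)
        r2 = (revcomp(frag), "I" * 20)
        assert merge_pair(r1, r2)[0] == "discarded"


class TestStitchPair:
    def test_junction_placement(self):
        a, b = _seq(_rng(7), 90), _seq(_rng(8), 90)
        out = stitch_pair((a, "I" * 90), (b, "I" * 90))
        seq, qual = out
        assert len(seq) == 200
        assert seq[90:110] == "A" * 20  # positions 91-110, 1-based
        assert seq[:90] == a and seq[110:] == revcomp(b)
        assert qual[90:110] == "I" * 20

    def test_short_mate_discarded(self):
        a, b = _seq(_rng(9), 90), _seq(_rng(10), 20)
        assert stitch_pair((a, "I" * 90), (b, "I" * 20)) is None


class TestPairwiseIdentity:
    def test_identical(self):
        s = _seq(_rng(11), 100)
        assert pairwise_identity(s, s) == 1.0

    def test_two_mismatches_in_32mer(self):
        s = _seq(_rng(12), 32)
        t = list(s)
        t[5] = "A" if s[5] != "A" else "C"
        t[20] = "A" if s[20] != "A" else "C"
        ident = pairwise_identity(s, "".join(t))
        assert ident == pytest.approx(30 / 32)
        assert ident >= 0.93  # must co-cluster at the default threshold

    def test_single_insertion(self):
        s = _seq(_rng(13), 100)
        t = s[:50] + "A" + s[50:] if s[49] != "A" else s[:50] + "C" + s[50:]
        assert pairwise_identity(s, t) == pytest.approx(100 / 101)

    def test_symmetry_and_substitution_identity(self):
        rng = _rng(14)
        for _ in range(20):
            n = int(rng.integers(32, 200))
            s = _seq(rng, n)
            k = int(rng.integers(0, 4))
            pos = rng.choice(n, size=k, replace=False)
            t = list(s)
            for p in pos:
                t[p] = "A" if s[p] != "A" else "C"
            t = "".join(t)
            assert pairwise_identity(s, t) == pytest.approx((n - k) / n)
            assert pairwise_identity(s, t) == pairwise_identity(t, s)

    def test_agrees_with_dp_distance_oracle(self):
        rng = _rng(15)
        for _ in range(15):
            n = int(rng.integers(20, 80))
            s = _seq(rng, n)
            # derive t by random edits
            t = list(s)
            for _ in range(int(rng.integers(0, 5))):
                op = rng.integers(0, 3)
                p = int(rng.integers(0, len(t)))
                if op == 0:
                    t[p] = "ACGT"[rng.integers(0, 4)]
                elif op == 1 and len(t) > 10:
                    del t[p]
                else:
                    t.insert(p, "ACGT"[rng.integers(0, 4)])
            t = "".join(t)
            short, long_ = (s, t) if len(s) <= len(t) else (t, s)
            d = semiglobal_distance(short, long_)
            ident = pairwise_identity(s, t)
            # identity derived from a minimum-edit path: columns <= len(short)+d
            assert ident >= (len(short) - d) / (len(short) + d) - 1e-9
            if d == 0:
                assert ident == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_identical_reads_one_centroid(self):
        s = _seq(_rng(16), 100)
        cents = greedy_cluster([(f"r{i}", s) for i in range(10)])
        assert len(cents) == 1 and cents[0].member_count == 10

    def test_dissimilar_sequences_stay_apart(self):
        rng = _rng(17)
        s = _seq(rng, 100)
        t = list(s)
        idx = rng.choice(100, size=15, replace=False)  # 85% identity
        for p in idx:
            t[p] = "A" if s[p] != "A" else "C"
        t = "".join(t)
        assert pairwise_identity(s, t) == pytest.approx(0.85)
        assert len(greedy_cluster([("a", s), ("b", t)], threshold=0.93)) == 2

    def test_32mers_within_two_mismatches_co_cluster(self):
        s = _seq(_rng(18), 32)
        t = list(s)
        t[3] = "A" if s[3] != "A" else "C"
        t[30] = "A" if s[30] != "A" else "C"
        cents = greedy_cluster([("a", s), ("b", "".join(t))], threshold=0.93)
        assert len(cents) == 1

    def test_partition_property(self):
        rng = _rng(19)
        frags = [_seq(rng, int(rng.integers(40, 200))) for _ in range(8)]
        reads = []
        for i, f in enumerate(frags):
            for j in range(int(rng.integers(1, 6))):
                reads.append((f"r{i}_{j}", f))
        cents = greedy_cluster(reads)
        assert sum(c.member_count for c in cents) == len(reads)

    def test_threshold_monotonicity(self):
        rng = _rng(20)
        base = [_seq(rng, 80) for _ in range(6)]
        reads = []
        for i, f in enumerate(base):
            for j in range(4):
                t = list(f)
                for p in rng.choice(80, size=int(rng.integers(0, 8)), replace=False):
                    t[p] = "ACGT"[rng.integers(0, 4)]
                reads.append((f"r{i}_{j}", "".join(t)))
        counts = [
            len(greedy_cluster(reads, threshold=t))
            for t in (0.80, 0.85, 0.90, 0.93, 0.97, 1.0)
        ]
        assert counts == sorted(counts)

    def test_empty_input(self):
        assert greedy_cluster([]) == []


class TestBuildMockReference:
    def _per_geno(self, rng, n_frags=3, genotypes=("g1",)):
        frags = [_seq(rng, int(rng.integers(60, 200))) for _ in range(n_frags)]
        out = {}
        for g in genotypes:
            reads = []
            for i, f in enumerate(frags):
                for j in range(5):
                    reads.append((f"{g}_r{i}_{j}", f, "I" * len(f)))
            out[g] = [
                __import__("gbsnp.mock_reference", fromlist=["MergedRead"]).MergedRead(
                    rid, s, q, "assembled"
                )
                for rid, s, q in reads
            ]
        return frags, out

    def test_distinct_fragments_give_distinct_centroids(self):
        frags, per_geno = self._per_geno(_rng(21))
        mock = build_mock_reference(per_geno, ["g1"])
        assert len(mock.centroids) == len(frags)
        assert sorted(c.seq for c in mock.centroids) == sorted(frags)

    def test_across_genotype_idempotence(self):
        frags, per_geno = self._per_geno(_rng(22), genotypes=("g1", "g2"))
        solo = build_mock_reference({"g1": per_geno["g1"]}, ["g1"])
        both = build_mock_reference(per_geno, ["g1", "g2"])
        assert len(both.centroids) == len(solo.centroids)

    def test_genome_is_concatenation(self):
        _, per_geno = self._per_geno(_rng(23))
        mock = build_mock_reference(per_geno, ["g1"])
        assert len(mock.genome_seq) == sum(len(c.seq) for c in mock.centroids)

    def test_offsets_invertible(self):
        _, per_geno = self._per_geno(_rng(24))
        mock = build_mock_reference(per_geno, ["g1"])
        for cid, start, end in mock.offsets:
            for local in (1, end - start + 1):
                g = mock.to_genome_coord(cid, local)
                assert mock.from_genome_coord(g) == (cid, local)
        # genome coordinates tile without overlap
        spans = sorted((s, e) for _, s, e in mock.offsets)
        assert spans[0][0] == 1 and spans[-1][1] == len(mock.genome_seq)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1

    def test_empty_selection_is_error(self):
        with pytest.raises(ValueError):
            build_mock_reference({}, [])


class TestMergeAndStitch:
    def test_paths_are_disjoint_and_labelled(self):
        rng = _rng(25)
        pairs = []
        lens = [200, 250, 350, 400]
        frags = [_seq(rng, L) for L in lens]
        for i, f in enumerate(frags):
            r1, r2 = _reads_from_fragment(f)
            pairs.append((f"p{i}", r1, r2))
        merged = merge_and_stitch(pairs)
        by_id = {m.id: m for m in merged}
        assert by_id["p0"].origin == "assembled" and by_id["p0"].seq == frags[0]
        assert by_id["p2"].origin == "stitched"
        assert "A" * 20 in by_id["p2"].seq
        assert by_id["p2"].r1_len == 150

    def test_reconstruction_on_error_free_reads(self, tmp_path):
        """On error-free data every centroid is either an exact fragment
        sequence (merge path) or an exact R1 + 20A + rc(R2) construct."""
        from gbsnp import pipeline
        from gbsnp.synthetic_data import SimulationConfig, simulate

        cfg = SimulationConfig(
            n_fragments=25, n_genotypes=4, n_snps=0, mean_depth=20,
            error_rate_per_base=0.0, seed=31,
        )
        sim = simulate(cfg, outdir=tmp_path / "sim")
        result = pipeline.run_all(
            sim.r1_path, sim.r2_path, sim.barcode_path, tmp_path / "work"
        )
        fragments = set(sim.truth.fragments)
        stitch_constructs = set()
        for frag in sim.truth.fragments:
            for bc_len in range(6, 11):
                r1 = frag[: cfg.read_len - bc_len - 5]
                r2rc = frag[-(cfg.read_len - 3):]
                stitch_constructs.add(r1 + "A" * 20 + r2rc)
        for c in result.mock.centroids:
            assert c.seq in fragments or c.seq in stitch_constructs
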