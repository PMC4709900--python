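"""Stage 2: merge/stitch processed read pairs and cluster them into a mock reference.

Paired reads whose 3'(R1)-5'(rc R2) overlap is at least 10 bp are merged into a
single full-fragment sequence; pairs without sufficient overlap (long fragments)
are stitched as R1 + 20 A's + rc(R2). The pooled merged/stitched reads are then
greedily clustered at a nucleotide identity threshold (default 93%, which lets
the shortest 32 bp reads differ at up to two positions) and the cluster
representatives (centroids), concatenated in order, form the mock reference
"genome" used for read mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .dna import encode, revcomp
from . import io as gio

STITCH_JUNCTION = "A" * 20
STITCH_QUAL = "I" * 20  # Phred 40


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    origin: str  # "assembled" | "stitched"
    r1_len: Optional[int] = None  # stitched reads: R1 part length (junction offset)


@dataclass
class Centroid:
    id: str
    seq: str
    member_count: int = 1
    members: list = field(default_factory=list)
    source_genotypes: set = field(default_factory=set)


def merge_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_len: int = 32,
) -> tuple[str, Optional[tuple[str, str]]]:
    """Overlap-merge a read pair into a full-fragment sequence.

    R2 is reverse-complemented into R1 orientation, the longest 3'(R1)-5'(rcR2)
    overlap of >= min_overlap bases with mismatch fraction <= max_mismatch_frac
    is taken, and mismatching columns are resolved toward the higher-quality
    base (tie -> R1). Returns (status, (seq, qual)) with status one of
    "merged", "unmerged" (no acceptable overlap) or "discarded" (merged product
    shorter than min_len).
    """
    s1, q1 = r1
    s2, q2 = revcomp(r2[0]), r2[1][::-1]
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return "unmerged", None
    max_l = min(n1, n2)

    # candidate overlap lengths from exact seed probes, then exhaustive fallback
    cands: list[int] = []
    probe_len = min(16, n2)
    for off in (0, probe_len):
        if off + probe_len > n2:
            break
        probe = s2[off : off + probe_len]
        start = 0
        while True:
            i = s1.find(probe, start)
            if i < 0:
                break
            L = n1 - i + off
            if min_overlap <= L <= max_l:
                cands.append(L)
            start = i + 1
    cands = sorted(set(cands), reverse=True)

    a1, a2 = encode(s1), encode(s2)

    def mismatches(L: int) -> int:
        return int(np.count_nonzero(a1[n1 - L :] != a2[:L]))

    best = None
    for L in cands:
        if mismatches(L) <= max_mismatch_frac * L:
            best = L
            break
    if best is None:
        for L in range(max_l, min_overlap - 1, -1):
            if mismatches(L) <= max_mismatch_frac * L:
                best = L
                break
    if best is None:
        return "unmerged", None

    L = best
    ov1, ov2 = list(s1[n1 - L :]), s2[:L]
    ovq1, ovq2 = list(q1[n1 - L :]), q2[:L]
    for k in range(L):
        if ov1[k] != ov2[k] and ovq2[k] > ovq1[k]:
            ov1[k] = ov2[k]
            ovq1[k] = ovq2[k]
    seq = s1[: n1 - L] + "".join(ov1) + s2[L:]
    qual = q1[: n1 - L] + "".join(ovq1) + q2[L:]
    if len(seq) < min_len:
        return "discarded", None
    return "merged", (seq, qual)


def stitch_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_len_each: int = 32,
) -> Optional[tuple[str, str]]:
    """Join an unmerged pair as R1 + 20 high-quality A's + rc(R2), or None if
    either mate is shorter than min_len_each."""
    s1, q1 = r1
    s2, q2 = r2
    if len(s1) < min_len_each or len(s2) < min_len_each:
        return None
    return s1 + STITCH_JUNCTION + revcomp(s2), q1 + STITCH_QUAL + q2[::-1]


def merge_and_stitch(
    pairs: Iterable[tuple[str, tuple[str, str], tuple[str, str]]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_len: int = 32,
) -> list[MergedRead]:
    """Merge every pair that overlaps, stitch the rest; returns MergedReads.

    Unmerged pairs where one mate is nonetheless contained in the other at
    high identity (a short fragment whose adapter tail escaped trimming) are
    discarded rather than stitched: stitching them would duplicate the
    fragment inside one read and poison the centroid set.
    """
    out = []
    for rid, r1, r2 in pairs:
        status, merged = merge_pair(r1, r2, min_overlap, max_mismatch_frac, min_len)
        if status == "merged":
            out.append(MergedRead(rid, merged[0], merged[1], "assembled"))
        elif status == "unmerged":
            rc2 = revcomp(r2[0])
            s, l = (r1[0], rc2) if len(r1[0]) <= len(rc2) else (rc2, r1[0])
            if s:
                k = max(1, int(0.12 * len(s)))
                res = edlib.align(s, l, mode="HW", task="distance", k=k)
                if res["editDistance"] >= 0:
                    continue  # mate containment: ambiguous structure, drop pair
            st = stitch_pair(r1, r2, min_len)
            if st is not None:
                out.append(MergedRead(rid, st[0], st[1], "stitched", r1_len=len(r1[0])))
    return out


def _cigar_identity(cigar: str) -> float:
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matched columns in an optimal end-free alignment.

    The shorter sequence is aligned within the longer with free terminal gaps
    on the longer sequence; gap columns inside the alignment count as
    mismatches. Symmetric; 1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    s, l = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(s, l, mode="HW", task="path")
    return _cigar_identity(res["cigar"])


def greedy_cluster(
    reads: Sequence[tuple[str, str]],
    threshold: float = 0.93,
    best_fit: bool = False,
) -> list[Centroid]:
    """Greedy length-sorted clustering of (id, seq) reads at an identity threshold.

    Reads are processed longest first (ties lexicographic by sequence then id);
    each read joins the first (or best, with best_fit) existing centroid whose
    pairwise identity meets the threshold, otherwise founds a new centroid with
    itself as the representative sequence.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(reads, key=lambda r: (-len(r[1]), r[1], r[0]))
    # dereplicate exact duplicates; first occurrence in order founds the group
    groups: dict[str, list[str]] = {}
    for rid, seq in order:
        groups.setdefault(seq, []).append(rid)

    centroids: list[Centroid] = []
    for seq, rids in groups.items():
        n = len(rids)
        best_c, best_ident = None, threshold
        for c in centroids:
            short = min(len(seq), len(c.seq))
            k = int((1 - threshold) / threshold * short) + 1
            res = edlib.align(
                *((seq, c.seq) if len(seq) <= len(c.seq) else (c.seq, seq)),
                mode="HW", task="distance", k=k,
            )
            if res["editDistance"] < 0:
                continue
            if res["editDistance"] == 0:
                ident = 1.0
            else:
                ident = pairwise_identity(seq, c.seq)
            if ident >= best_ident if best_fit else ident >= threshold:
                if best_fit:
                    best_c, best_ident = c, ident
                else:
                    best_c = c
                    break
        if best_c is not None:
            best_c.member_count += n
            best_c.members.extend(rids)
        else:
            centroids.append(Centroid(id=rids[0], seq=seq, member_count=n, members=list(rids)))
    return centroids


@dataclass
class MockReference:
    """Ordered centroid set plus the concatenated single-sequence 'genome'.

    Offsets are 1-based inclusive intervals on the concatenated sequence, tiling
    it without overlap, so any genome coordinate maps back to exactly one
    (centroid, local position) and forward again to itself.
    """

    centroids: list[Centroid]
    genome_name: str = "MockRefGenome"

    def __post_init__(self):
        self.offsets: list[tuple[str, int, int]] = []
        pos = 1
        for c in self.centroids:
            self.offsets.append((c.id, pos, pos + len(c.seq) - 1))
            pos += len(c.seq)

    @property
    def genome_seq(self) -> str:
        return "".join(c.seq for c in self.centroids)

    def to_genome_coord(self, centroid_id: str, local_pos: int) -> int:
        """(centroid, 1-based local position) -> 1-based genome coordinate."""
        for cid, start, end in self.offsets:
            if cid == centroid_id:
                if not 1 <= local_pos <= end - start + 1:
                    raise ValueError(f"position {local_pos} outside centroid {cid}")
                return start + local_pos - 1
        raise KeyError(centroid_id)

    def from_genome_coord(self, pos: int) -> tuple[str, int]:
        """1-based genome coordinate -> (centroid_id, 1-based local position)."""
        for cid, start, end in self.offsets:
            if start <= pos <= end:
                return cid, pos - start + 1
        raise ValueError(f"genome position {pos} out of range")

    def write_fasta(self, genome_path, clusters_path) -> None:
        gio.write_fasta(genome_path, [(self.genome_name, self.genome_seq)])
        gio.write_fasta(clusters_path, [(c.id, c.seq) for c in self.centroids])

    def write_membership(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcentroid_id\n")
            for c in self.centroids:
                for rid in c.members:
                    fh.write(f"{rid}\t{c.id}\n")


def build_mock_reference(
    per_genotype_reads: dict[str, list[MergedRead]],
    selected: Sequence[str],
    threshold: float = 0.93,
    best_fit: bool = False,
) -> MockReference:
    """Cluster merged/stitched reads within each selected genotype, then (for
    more than one selected genotype) cluster the pooled genotype-specific
    centroids into the master centroid set."""
    if not selected:
        raise ValueError("at least one genotype must be selected")
    missing = [g for g in selected if g not in per_genotype_reads]
    if missing:
        raise KeyError(f"selected genotypes without reads: {missing}")
    per_geno_centroids: dict[str, list[Centroid]] = {}
    for gid in selected:
        reads = [(m.id, m.seq) for m in per_genotype_reads[gid]]
        cents = greedy_cluster(reads, threshold, best_fit)
        for c in cents:
            c.source_genotypes = {gid}
        per_geno_centroids[gid] = cents
    if len(selected) == 1:
        final = per_geno_centroids[selected[0]]
    else:
        pooled = [c for gid in selected for c in per_geno_centroids[gid]]
        by_id = {c.id: c for c in pooled}
        master = greedy_cluster([(c.id, c.seq) for c in pooled], threshold, best_fit)
        for mc in master:
            mc.member_count = sum(by_id[r].member_count for r in mc.members)
            mc.source_genotypes = set().union(
                *(by_id[r].source_genotypes for r in mc.members)
            )
        final = master
    centroids = [
        Centroid(
            id=f"MR{i+1:06d}",
            seq=c.seq,
            member_count=c.member_count,
            members=c.members,
            source_genotypes=c.source_genotypes,
        )
        for i, c in enumerate(final)
    ]
    return MockReference(centroids)


def select_most_abundant(read_counts: dict[str, int], n: int = 1) -> list[str]:
    """Pick the n genotypes with the most parsed reads (ties by id for
    reproducibility)."""
    return [
        g for g, _ in sorted(read_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    ]
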