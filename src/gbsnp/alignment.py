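"""Stage 3: map processed read pairs to the (mock) reference and build pileups.

The built-in mapper indexes the reference with exact 20-mers, verifies seed
candidates by direct comparison (edlib fallback for gapped hits) and keeps a
pair only when both mates align uniquely to the same contig in opposite,
non-inverted orientations — reads with two or more distinct best-scoring loci
are treated as unmapped, emulating the exclusion of reads with secondary or
supplementary alignments. Per-genotype pileups count A/C/G/T depths at each
1-based position; bases in the mate-overlap region of a pair are counted once.
Externally produced samtools-mpileup text files can be ingested instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import edlib
import numpy as np

from .dna import BASES, encode, phred, revcomp
from . import io as gio
from .mock_reference import MockReference

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentRecord:
    read_id: str
    ref_id: str
    pos: int  # 1-based leftmost reference coordinate
    strand: str  # '+' or '-'
    cigar: str  # extended ops over the aligned span
    score: int  # edit distance
    mate_pos: int
    is_unique: bool
    seq: str = ""  # read sequence oriented to the reference strand
    qual: str = ""


@dataclass
class PileupColumn:
    ref_id: str
    pos: int  # 1-based
    ref_base: str
    depths: tuple[int, int, int, int]  # A, C, G, T
    indel_evidence: bool = False


class Reference:
    """Indexed mapping target: an ordered set of named contigs.

    For a mock reference the contigs are the individual centroids, which makes
    centroid boundaries impossible to cross by construction; internal runs of
    >= 20 A's (stitch junctions) are additionally located so alignments
    spanning both sides of a junction can be rejected.
    """

    def __init__(self, contigs: Sequence[tuple[str, str]], seed_len: int = 20,
                 max_seed_hits: int = 8):
        if not contigs:
            raise ValueError("empty reference")
        self.names = [n for n, _ in contigs]
        self.name_index = {n: i for i, n in enumerate(self.names)}
        if len(self.name_index) != len(self.names):
            raise ValueError("duplicate contig names in reference")
        self.seqs = [s.upper() for _, s in contigs]
        self.encoded = [encode(s) for s in self.seqs]
        self.seed_len = seed_len
        self._junctions = [
            [(m.start(), m.end() - 1) for m in re.finditer(r"A{20,}", s)]
            for s in self.seqs
        ]
        index: dict[str, list] = {}
        k = seed_len
        for ci, s in enumerate(self.seqs):
            for p in range(len(s) - k + 1):
                kmer = s[p : p + k]
                hits = index.get(kmer)
                if hits is None:
                    index[kmer] = [(ci, p)]
                elif len(hits) <= max_seed_hits:
                    hits.append((ci, p))
        # mask repetitive seeds (e.g. poly-A stitch junctions)
        self._index = {km: h for km, h in index.items() if len(h) <= max_seed_hits}

    @classmethod
    def from_mock(cls, mock: MockReference, **kw) -> "Reference":
        return cls([(c.id, c.seq) for c in mock.centroids], **kw)

    @classmethod
    def from_fasta(cls, path, **kw) -> "Reference":
        return cls(list(gio.read_fasta(path)), **kw)

    def length(self, ref_id: str) -> int:
        return len(self.seqs[self.names.index(ref_id)])


def _align_oriented(ref: Reference, seq: str, arr: np.ndarray, max_edits: int):
    """Best hits of one read orientation: list of (dist, ci, start, cigar)."""
    k = ref.seed_len
    n = len(seq)
    if n < k:
        return []
    offs = list(range(0, n - k + 1, k))
    if offs[-1] != n - k:
        offs.append(n - k)
    cand: set[tuple[int, int]] = set()
    gapped_contigs: set[int] = set()
    for off in offs:
        hits = ref._index.get(seq[off : off + k])
        if hits:
            for ci, p in hits:
                cand.add((ci, p - off))
                gapped_contigs.add(ci)
    best: list = []
    best_d = max_edits
    for ci, start in cand:
        enc = ref.encoded[ci]
        if start < 0 or start + n > enc.size:
            continue
        d = int(np.count_nonzero(arr != enc[start : start + n]))
        if d < best_d:
            best, best_d = [(d, ci, start, f"{n}M")], d
        elif d == best_d:
            best.append((d, ci, start, f"{n}M"))
    if not best:
        # gapped fallback against every seed-hit contig
        for ci in gapped_contigs:
            res = edlib.align(seq, ref.seqs[ci], mode="HW", task="path", k=max_edits)
            d = res["editDistance"]
            if d < 0:
                continue
            loc = res["locations"][0]
            if d < best_d:
                best, best_d = [(d, ci, loc[0], res["cigar"])], d
            elif d == best_d:
                best.append((d, ci, loc[0], res["cigar"]))
    return best


def align_read(read: tuple[str, str], ref: Reference, max_edit_frac: float = 0.07):
    """Align one read in both orientations.

    Returns (hits, stranded) where hits is the list of best-scoring
    (dist, contig_idx, start, cigar, strand, oriented_seq, oriented_qual).
    """
    seq, qual = read
    max_edits = int(max_edit_frac * len(seq))
    out = []
    best_d = None
    for strand, s, q in (("+", seq, qual), ("-", revcomp(seq), qual[::-1])):
        arr = encode(s)
        for d, ci, start, cig in _align_oriented(ref, s, arr, max_edits):
            if best_d is None or d < best_d:
                out, best_d = [(d, ci, start, cig, strand, s, q)], d
            elif d == best_d:
                out.append((d, ci, start, cig, strand, s, q))
    return out


def _span(hit) -> tuple[int, int, int]:
    """(contig, start, end) 0-based half-open reference span of a hit."""
    d, ci, start, cig, *_ = hit
    ref_len = 0
    for n, op in _CIG_RE.findall(cig):
        if op in "=XDM":
            ref_len += int(n)
    return ci, start, start + ref_len


def _crosses_junction(ref: Reference, ci: int, start: int, end: int) -> bool:
    for js, je in ref._junctions[ci]:
        if start < js and end > je + 1:
            return True
    return False


def map_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    ref: Reference,
    max_edit_frac: float = 0.07,
    read_id: str = "",
) -> Optional[tuple[AlignmentRecord, AlignmentRecord]]:
    """Map a read pair with pair-proper, unique-hit semantics.

    Both mates must have a single best-scoring locus, on the same contig, in
    opposite non-inverted orientations, not spanning a stitch junction;
    anything else is unmapped (None).
    """
    hits1 = align_read(r1, ref, max_edit_frac)
    hits2 = align_read(r2, ref, max_edit_frac)
    if len(hits1) != 1 or len(hits2) != 1:
        return None
    h1, h2 = hits1[0], hits2[0]
    ci1, s1, e1 = _span(h1)
    ci2, s2, e2 = _span(h2)
    if ci1 != ci2 or h1[4] == h2[4]:
        return None
    fwd, rev = (h1, h2) if h1[4] == "+" else (h2, h1)
    _, fs, fe = _span(fwd)
    _, rs, re_ = _span(rev)
    if not (fs <= rs and fe <= re_):
        return None  # inverted mate arrangement
    if _crosses_junction(ref, ci1, fs, fe) or _crosses_junction(ref, ci1, rs, re_):
        return None

    def rec(hit, other_start: int) -> AlignmentRecord:
        d, ci, start, cig, strand, s, q = hit
        return AlignmentRecord(
            read_id=read_id, ref_id=ref.names[ci], pos=start + 1, strand=strand,
            cigar=cig, score=d, mate_pos=other_start + 1, is_unique=True,
            seq=s, qual=q,
        )

    return rec(h1, _span(h2)[1]), rec(h2, _span(h1)[1])


def _aligned_bases(rec: AlignmentRecord, ref: Reference):
    """Per-base (ref_pos0, code, qual) arrays plus indel-evidence positions."""
    cig = _CIG_RE.findall(rec.cigar)
    if len(cig) == 1 and cig[0][1] in "M=":
        n = int(cig[0][0])
        pos = np.arange(rec.pos - 1, rec.pos - 1 + n)
        return pos, encode(rec.seq), phred(rec.qual), np.empty(0, dtype=np.int64)
    positions, codes, quals, indels = [], [], [], []
    rp, qp = rec.pos - 1, 0
    seq_codes = encode(rec.seq)
    q = phred(rec.qual)
    for n_s, op in cig:
        n = int(n_s)
        if op in "M=X":
            positions.extend(range(rp, rp + n))
            codes.extend(seq_codes[qp : qp + n])
            quals.extend(q[qp : qp + n])
            rp += n
            qp += n
        elif op == "D":
            indels.extend(range(rp, rp + n))
            rp += n
        elif op == "I":
            if rp - 1 >= 0:
                indels.append(rp - 1)
            indels.append(rp)
            qp += n
    return (
        np.asarray(positions, dtype=np.int64),
        np.asarray(codes, dtype=np.uint8),
        np.asarray(quals, dtype=np.int64),
        np.asarray(sorted(set(indels)), dtype=np.int64),
    )


class PileupEngine:
    """Accumulates one genotype's A/C/G/T depths per reference position."""

    def __init__(self, ref: Reference, min_base_q: int = 0):
        self.ref = ref
        self.min_base_q = min_base_q
        self.counts = [np.zeros((4, len(s)), dtype=np.int32) for s in ref.seqs]
        self.indel = [np.zeros(len(s), dtype=bool) for s in ref.seqs]

    def add_pair(self, pair: tuple[AlignmentRecord, AlignmentRecord]) -> None:
        a, b = pair
        ci = self.ref.name_index[a.ref_id]
        p1, c1, q1, i1 = _aligned_bases(a, self.ref)
        p2, c2, q2, i2 = _aligned_bases(b, self.ref)
        pos = np.concatenate([p1, p2])
        codes = np.concatenate([c1, c2])
        quals = np.concatenate([q1, q2])
        if p1.size and p2.size and max(p1[0], p2[0]) <= min(p1[-1], p2[-1]):
            # mate overlap: count each molecule position once, better quality wins
            rank = np.concatenate([np.zeros(p1.size), np.ones(p2.size)])
            order = np.lexsort((rank, -quals, pos))
            pos, codes, quals = pos[order], codes[order], quals[order]
            _, first = np.unique(pos, return_index=True)
            pos, codes, quals = pos[first], codes[first], quals[first]
        keep = (codes < 4) & (quals >= self.min_base_q)
        pos, codes = pos[keep], codes[keep]
        np.add.at(self.counts[ci], (codes, pos), 1)
        for ind in (i1, i2):
            if ind.size:
                valid = ind[ind < self.indel[ci].size]
                self.indel[ci][valid] = True

    def add_single(self, rec: AlignmentRecord) -> None:
        ci = self.ref.name_index[rec.ref_id]
        pos, codes, quals, ind = _aligned_bases(rec, self.ref)
        keep = (codes < 4) & (quals >= self.min_base_q)
        np.add.at(self.counts[ci], (codes[keep], pos[keep]), 1)
        if ind.size:
            self.indel[ci][ind[ind < self.indel[ci].size]] = True

    def columns(self) -> list[PileupColumn]:
        out = []
        for ci, name in enumerate(self.ref.names):
            depth = self.counts[ci]
            covered = np.flatnonzero((depth.sum(axis=0) > 0) | self.indel[ci])
            seq = self.ref.seqs[ci]
            for p in covered:
                out.append(
                    PileupColumn(
                        ref_id=name,
                        pos=int(p) + 1,
                        ref_base=seq[p],
                        depths=tuple(int(x) for x in depth[:, p]),
                        indel_evidence=bool(self.indel[ci][p]),
                    )
                )
        return out


def pileup(
    pairs: Iterable[tuple[AlignmentRecord, AlignmentRecord]],
    ref: Reference,
    min_base_q: int = 0,
) -> list[PileupColumn]:
    """Pile up a genotype's retained pairs into per-position base counts."""
    eng = PileupEngine(ref, min_base_q)
    for pair in pairs:
        eng.add_pair(pair)
    return eng.columns()


_BASE_SET = set("ACGT")


def read_external_pileup(path) -> list[PileupColumn]:
    """Parse a samtools-mpileup text file into pileup columns.

    Handles '.'/',' reference matches, case-folded substitutions, '^'+mapq,
    '$', '+n[seq]'/'-n[seq]' indels and '*' deletion placeholders. A malformed
    bases string or a depth mismatch raises ValueError naming the line.
    """
    cols = []
    with gio.open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >=5 tab-separated fields")
            ref_id, pos_s, ref_base, depth_s, bases = parts[0], parts[1], parts[2], parts[3], parts[4]
            ref_base = ref_base.upper()
            depth = int(depth_s)
            counts = {b: 0 for b in BASES}
            indel = False
            resolved = 0
            i, n = 0, len(bases)
            while i < n:
                ch = bases[i]
                if ch == "^":
                    if i + 1 >= n:
                        raise ValueError(f"{path}:{ln}: dangling '^' mapping quality")
                    i += 2
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < n and bases[j].isdigit():
                        j += 1
                    if j == i + 1:
                        raise ValueError(f"{path}:{ln}: indel marker without length")
                    length = int(bases[i + 1 : j])
                    if j + length > n:
                        raise ValueError(f"{path}:{ln}: dangling indel sequence")
                    indel = True
                    i = j + length
                    continue
                if ch in ".,":
                    if ref_base in _BASE_SET:
                        counts[ref_base] += 1
                    resolved += 1
                elif ch.upper() in _BASE_SET:
                    counts[ch.upper()] += 1
                    resolved += 1
                elif ch == "*":
                    indel = True
                    resolved += 1
                elif ch in "Nn><":
                    resolved += 1
                else:
                    raise ValueError(f"{path}:{ln}: unexpected symbol {ch!r} in bases string")
                i += 1
            if resolved != depth:
                raise ValueError(
                    f"{path}:{ln}: bases string resolves {resolved} reads, depth column says {depth}"
                )
            cols.append(
                PileupColumn(
                    ref_id=ref_id,
                    pos=int(pos_s),
                    ref_base=ref_base,
                    depths=(counts["A"], counts["C"], counts["G"], counts["T"]),
                    indel_evidence=indel,
                )
            )
    return cols


def write_pileup(cols: Iterable[PileupColumn], path) -> None:
    """Write pileup columns back out in the mpileup text dialect (forward
    strand, uniform 'I' base qualities); lossless for depths and indel flags."""
    with gio.open_text(path, "wt") as fh:
        for c in cols:
            parts = []
            for base, d in zip(BASES, c.depths):
                parts.append(("." if base == c.ref_base else base) * d)
            if c.indel_evidence:
                parts.append("+1A")
            bases = "".join(parts)
            depth = sum(c.depths)
            fh.write(f"{c.ref_id}\t{c.pos}\t{c.ref_base}\t{depth}\t{bases}\t{'I'*depth}\n")


def _sam_cigar(cigar: str) -> str:
    out = []
    for n, op in _CIG_RE.findall(cigar):
        out.append(n + ("M" if op in "=XM" else op))
    return "".join(out)


def write_sam(
    pairs: Iterable[tuple[AlignmentRecord, AlignmentRecord]],
    ref: Reference,
    path,
) -> None:
    """Minimal SAM export of retained pairs (@HD/@SQ header + 11 columns)."""
    with gio.open_text(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in zip(ref.names, ref.seqs):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for a, b in pairs:
            for rec, mate, first in ((a, b, True), (b, a, False)):
                flag = 0x1 | 0x2
                flag |= 0x40 if first else 0x80
                if rec.strand == "-":
                    flag |= 0x10
                if mate.strand == "-":
                    flag |= 0x20
                # seq/qual are stored reference-oriented, matching SAM convention
                fh.write(
                    "\t".join(
                        [
                            rec.read_id or "*",
                            str(flag),
                            rec.ref_id,
                            str(rec.pos),
                            "60",
                            _sam_cigar(rec.cigar),
                            "=",
                            str(mate.pos),
                            "0",
                            rec.seq or "*",
                            rec.qual or "*",
                        ]
                    )
                    + "\n"
                )
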