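"""Stage 1: parse raw multiplexed paired-end GBS reads and demultiplex per genotype.

Raw R1 reads are expected to start with a 6-10 bp in-line barcode followed by the
cut-site remnant of the rare cutter (PstI "TGCAG" by default); R2 reads start with
the common-cutter remnant (MspI "CCG"). Barcodes are recognised with at most one
mismatch, cut-site remnants exactly. Fragments shorter than the read length are
detected by the in-line adapter signature (reverse-complemented remnant of the
opposite cutter followed by the Illumina common adapter) and truncated there.
Quality trimming follows the LEADING / TRAILING / SLIDINGWINDOW / MINLEN scheme
with defaults 30/30/4:30/32.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .dna import hamming, phred, revcomp
from . import io as gio

# first 12 bases of the Illumina TruSeq common adapter
ILLUMINA_COMMON_ADAPTER = "AGATCGGAAGAG"


@dataclass(frozen=True)
class EnzymePair:
    """Cut-site remnants of a two-enzyme GBS protocol (defaults: PstI / MspI)."""

    rare_remnant: str = "TGCAG"
    common_remnant: str = "CCG"
    adapter: str = ILLUMINA_COMMON_ADAPTER

    def __post_init__(self):
        for s in (self.rare_remnant, self.common_remnant):
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"remnant must be non-empty uppercase ACGT: {s!r}")

    @property
    def r1_adapter_signature(self) -> str:
        """3' signature on R1: rc(common remnant) + adapter prefix."""
        return revcomp(self.common_remnant) + self.adapter[:12]

    def r2_adapter_signature(self, barcode: str) -> str:
        """3' signature on R2: rc(rare remnant) + rc(barcode) — the read-through
        structure on the barcoded side of the fragment."""
        return revcomp(self.rare_remnant) + revcomp(barcode)


class BarcodeTable:
    """Barcode -> genotype-ID map driving parsing and demultiplexing.

    Barcodes must be 6-10 bp, unique, and any two same-length barcodes must be
    at Hamming distance >= 2 (otherwise one-mismatch assignment is ambiguous).
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries = [(bc.upper(), gid) for bc, gid in entries]
        if not self.entries:
            raise ValueError("empty barcode table")
        barcodes = [bc for bc, _ in self.entries]
        gids = [g for _, g in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in table")
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate genotype ids in table")
        for bc in barcodes:
            if not (6 <= len(bc) <= 10) or set(bc) - set("ACGT"):
                raise ValueError(f"invalid barcode {bc!r} (need 6-10 bp ACGT)")
        by_len = defaultdict(list)
        for bc in barcodes:
            by_len[len(bc)].append(bc)
        for same in by_len.values():
            for i, a in enumerate(same):
                for b in same[i + 1 :]:
                    if hamming(a, b) <= 1:
                        raise ValueError(
                            f"barcodes {a} and {b} are within Hamming distance 1; "
                            "one-mismatch assignment would be ambiguous"
                        )
        self._exact = {bc: gid for bc, gid in self.entries}
        self._lengths = sorted(by_len, reverse=True)  # longest-first evaluation
        self._by_len = {L: [bc for bc in by_len[L]] for L in self._lengths}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genotype_ids(self) -> list[str]:
        return [gid for _, gid in self.entries]

    def genotype_of(self, barcode: str) -> str:
        return self._exact[barcode]

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        entries = []
        with gio.open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
                entries.append((parts[0], parts[1]))
        return cls(entries)

    def to_tsv(self, path) -> None:
        with gio.open_text(path, "wt") as fh:
            for bc, gid in self.entries:
                fh.write(f"{bc}\t{gid}\n")


def match_barcode(
    r1_prefix: str,
    table: BarcodeTable,
    enz: EnzymePair,
    max_mismatch: int = 1,
) -> Optional[tuple[str, str]]:
    """Identify the barcode at the 5' end of an R1 read.

    A barcode matches when its Hamming distance to the same-length read prefix
    is <= max_mismatch AND the bases following it equal the rare-cutter remnant
    exactly. Longest barcodes are evaluated first; an ambiguous tie between
    equal-length barcodes at equal distance is a no-match.

    Returns (genotype_id, barcode) or None.
    """
    remnant = enz.rare_remnant
    rlen = len(remnant)
    for L in table._lengths:
        if len(r1_prefix) < L + rlen:
            continue
        if r1_prefix[L : L + rlen] != remnant:
            continue
        prefix = r1_prefix[:L]
        gid = table._exact.get(prefix)
        if gid is not None:
            return gid, prefix
        if max_mismatch >= 1:
            best, best_d, ties = None, max_mismatch + 1, 0
            for bc in table._by_len[L]:
                d = hamming(prefix, bc)
                if d < best_d:
                    best, best_d, ties = bc, d, 1
                elif d == best_d:
                    ties += 1
            if best is not None and best_d <= max_mismatch:
                if ties > 1:
                    return None  # ambiguous across equal-length barcodes
                return table._exact[best], best
    return None


@dataclass
class ParseStats:
    """Read-pair accounting for the parsing step (conservation checked)."""

    total_pairs: int = 0
    barcode_matched: int = 0
    cutsite_failed: int = 0  # no barcode/cut-site structure found
    n_culled: int = 0  # majority-N pairs
    retained: int = 0

    def check(self) -> None:
        if self.retained + self.cutsite_failed + self.n_culled != self.total_pairs:
            raise AssertionError("ParseStats do not conserve read pairs")
        if self.barcode_matched != self.retained + self.n_culled:
            raise AssertionError("barcode_matched inconsistent")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("total_pairs", "barcode_matched", "cutsite_failed", "n_culled", "retained"):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def _majority_n(seq: str) -> bool:
    # strictly more than 50% uncalled bases
    return seq.count("N") * 2 > len(seq)


def _truncate_adapter(
    seq: str, qual: str, signature: str, min_partial: int = 4
) -> tuple[str, str]:
    """Cut a read at the leftmost adapter-signature occurrence.

    Falls back to a split-seed search tolerating up to 2 mismatches within the
    signature (sequencing errors must not leave adapter tails behind), then to
    a partial signature prefix (>= min_partial bases) hanging off the 3' end.
    """
    i = seq.find(signature)
    if i >= 0:
        return seq[:i], qual[:i]
    half = len(signature) // 2
    best = len(seq) + 1
    for off, probe in ((0, signature[:half]), (half, signature[half:])):
        start = 0
        while True:
            j = seq.find(probe, start)
            if j < 0:
                break
            anchor = j - off
            if 0 <= anchor < best and anchor + len(signature) <= len(seq):
                mism = sum(a != b for a, b in zip(seq[anchor:], signature))
                if mism <= 2:
                    best = anchor
            start = j + 1
    if best <= len(seq):
        return seq[:best], qual[:best]
    for k in range(min(len(signature) - 1, len(seq)), min_partial - 1, -1):
        if seq.endswith(signature[:k]):
            return seq[:-k], qual[:-k]
    return seq, qual


def parse_pair(
    read_id: str,
    r1: tuple[str, str],
    r2: tuple[str, str],
    table: BarcodeTable,
    enz: EnzymePair,
    max_mismatch: int = 1,
    keep_remnant: bool = False,
    require_r2_remnant: bool = False,
):
    """Parse one raw read pair.

    Returns (genotype_id, barcode, (seq1, qual1), (seq2, qual2)) on success or
    (None, reason, None, None) where reason is "barcode_fail" or "n_cull".
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    m = match_barcode(seq1, table, enz, max_mismatch)
    if m is None:
        return None, "barcode_fail", None, None
    gid, barcode = m
    cut = len(barcode) if keep_remnant else len(barcode) + len(enz.rare_remnant)
    seq1, qual1 = seq1[cut:], qual1[cut:]
    k = len(enz.common_remnant)
    r2_has_remnant = len(seq2) >= k and hamming(seq2[:k], enz.common_remnant) <= 1
    if require_r2_remnant and not r2_has_remnant:
        return None, "barcode_fail", None, None
    if not keep_remnant and r2_has_remnant:
        seq2, qual2 = seq2[k:], qual2[k:]
    # in-line adapter: truncate at the leftmost signature occurrence; a partial
    # signature at the very 3' end (fragment length near the read length) is
    # trimmed too when at least 4 of its bases are present
    seq1, qual1 = _truncate_adapter(seq1, qual1, enz.r1_adapter_signature)
    seq2, qual2 = _truncate_adapter(seq2, qual2, enz.r2_adapter_signature(barcode))
    if _majority_n(seq1) or _majority_n(seq2):
        return None, "n_cull", None, None
    return gid, barcode, (seq1, qual1), (seq2, qual2)


def quality_trim(
    seq: str,
    qual: str,
    window: int = 4,
    min_q: int = 30,
    lead_q: int = 30,
    trail_q: int = 30,
    min_len: int = 32,
) -> Optional[tuple[str, str]]:
    """LEADING/TRAILING/SLIDINGWINDOW/MINLEN quality trimming.

    Leading and trailing bases below lead_q/trail_q are removed; the read is
    then scanned 5'->3' in sliding windows of `window` bases and cut at the
    first window whose mean Phred falls below min_q, keeping any immediately
    following bases that individually meet min_q. Reads shorter than min_len
    after trimming are discarded (None).
    """
    if not seq:
        return None
    # fast path: nothing to do when every base is comfortably above threshold
    thresh_char = chr(33 + max(min_q, lead_q, trail_q))
    if min(qual) >= thresh_char:
        return (seq, qual) if len(seq) >= min_len else None
    q = phred(qual)
    good_lead = np.flatnonzero(q >= lead_q)
    if good_lead.size == 0:
        return None
    start = good_lead[0]
    good_trail = np.flatnonzero(q >= trail_q)
    end = good_trail[-1] + 1
    if end - start < 1:
        return None
    q = q[start:end]
    n = q.size
    if n >= window:
        csum = np.concatenate(([0], np.cumsum(q)))
        means = (csum[window:] - csum[:-window]) / window
        bad = np.flatnonzero(means < min_q)
        if bad.size:
            cut = int(bad[0])
            while cut < n and q[cut] >= min_q:
                cut += 1
            q = q[:cut]
            n = cut
    seq, qual = seq[start : start + n], qual[start : start + n]
    if len(seq) < min_len:
        return None
    return seq, qual


def parse_fastq_pair_files(
    r1_path,
    r2_path,
    table: BarcodeTable,
    enz: EnzymePair,
    max_mismatch: int = 1,
    keep_remnant: bool = False,
    require_r2_remnant: bool = False,
) -> tuple[Iterator, ParseStats]:
    """Parse two synchronized raw FASTQ files.

    Returns (records, stats): records is a generator of
    (read_id, genotype_id, barcode, (seq1,qual1), (seq2,qual2)); stats is
    filled in as the generator is consumed.
    """
    stats = ParseStats()

    def gen():
        for (t1, s1, q1), (t2, s2, q2) in zip(
            gio.read_fastq(r1_path), gio.read_fastq(r2_path)
        ):
            stats.total_pairs += 1
            rid = t1.split()[0]
            gid, info, p1, p2 = parse_pair(
                rid, (s1, q1), (s2, q2), table, enz,
                max_mismatch=max_mismatch,
                keep_remnant=keep_remnant,
                require_r2_remnant=require_r2_remnant,
            )
            if gid is None:
                if info == "barcode_fail":
                    stats.cutsite_failed += 1
                else:
                    stats.barcode_matched += 1
                    stats.n_culled += 1
                continue
            stats.barcode_matched += 1
            stats.retained += 1
            yield rid, gid, info, p1, p2

    return gen(), stats


@dataclass
class TrimStats:
    pairs_in: int = 0
    pairs_kept: int = 0
    orphans: int = 0
    pairs_dropped: int = 0


def demultiplex(
    records: Iterable,
    table: BarcodeTable,
    outdir,
    trim: bool = True,
    window: int = 4,
    min_q: int = 30,
    lead_q: int = 30,
    trail_q: int = 30,
    min_len: int = 32,
    suffix: str = ".fastq",
) -> tuple[dict[str, tuple[Path, Path]], Path, TrimStats]:
    """Quality-trim parsed read pairs and route them into per-genotype files.

    Every surviving pair goes to exactly one genotype's (R1, R2) file pair with
    mate order preserved; a mate whose partner was culled by quality trimming
    goes to a shared singles file. Returns (per-genotype paths, singles path,
    TrimStats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tstats = TrimStats()
    handles: dict[str, tuple] = {}
    paths: dict[str, tuple[Path, Path]] = {}
    for gid in table.genotype_ids:
        p1 = outdir / f"{gid}.R1{suffix}"
        p2 = outdir / f"{gid}.R2{suffix}"
        paths[gid] = (p1, p2)
        handles[gid] = (gio.open_text(p1, "wt"), gio.open_text(p2, "wt"))
    singles_path = outdir / f"singles{suffix}"
    singles = gio.open_text(singles_path, "wt")
    try:
        for rid, gid, barcode, (s1, q1), (s2, q2) in records:
            if gid not in handles:
                raise KeyError(f"record {rid} routed to unknown genotype {gid!r}")
            tstats.pairs_in += 1
            if trim:
                t1 = quality_trim(s1, q1, window, min_q, lead_q, trail_q, min_len)
                t2 = quality_trim(s2, q2, window, min_q, lead_q, trail_q, min_len)
            else:
                t1, t2 = (s1, q1), (s2, q2)
            title = f"{rid} BC:{barcode}"
            if t1 and t2:
                tstats.pairs_kept += 1
                h1, h2 = handles[gid]
                h1.write(f"@{title}\n{t1[0]}\n+\n{t1[1]}\n")
                h2.write(f"@{title}\n{t2[0]}\n+\n{t2[1]}\n")
            elif t1 or t2:
                tstats.orphans += 1
                s, q = t1 if t1 else t2
                singles.write(f"@{title}\n{s}\n+\n{q}\n")
            else:
                tstats.pairs_dropped += 1
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()
        singles.close()
    return paths, singles_path, tstats
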