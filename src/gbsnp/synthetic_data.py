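"""End-to-end GBS experiment simulator with full truth tables.

Emulates a two-enzyme (PstI/MspI-style) reduced-representation library:
random restriction fragments, a panel of genotypes with planted bi-allelic
SNPs, and barcoded 150 bp paired-end reads (R1 = barcode + rare-cutter remnant
+ fragment prefix, R2 = common-cutter remnant + reverse-complemented fragment
suffix). Fragments shorter than the read length read through into the adapter.
Per-base substitution errors are uniform; per-fragment depth is Poisson.
Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dna import BASES, revcomp
from .fastq_processing import BarcodeTable, EnzymePair, ILLUMINA_COMMON_ADAPTER
from . import io as gio

# long-enough adapter tail for full read-through of short fragments
_ADAPTER_TAIL = (ILLUMINA_COMMON_ADAPTER + "ACACGTCTGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG") * 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated GBS experiment."""

    n_fragments: int = 300
    fragment_len_range: tuple[int, int] = (120, 400)
    n_genotypes: int = 24
    n_snps: int = 150
    het_fraction: float = 0.3
    read_len: int = 150
    mean_depth: float = 40.0
    error_rate_per_base: float = 0.002
    n_replicates: int = 0  # extra re-sequencings of the first genotype
    seed: int = 0

    def __post_init__(self):
        if min(self.n_fragments, self.n_genotypes, self.read_len) <= 0:
            raise ValueError("sizes must be positive")
        if self.mean_depth <= 0 or not 0 <= self.error_rate_per_base < 1:
            raise ValueError("invalid depth or error rate")
        lo, hi = self.fragment_len_range
        if not 0 < lo <= hi:
            raise ValueError("invalid fragment length range")


@dataclass
class TruthTable:
    fragments: list[str]
    #: (fragment_index, 0-based offset, ref base, alt base) per planted SNP
    snps: list[tuple[int, int, str, str]]
    #: genotype x SNP true states: 0 hom-ref, 1 het, 2 hom-alt
    states: np.ndarray
    genotype_ids: list[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        with open(outdir / "truth_fragments.tsv", "w") as fh:
            for i, seq in enumerate(self.fragments):
                fh.write(f"F{i:04d}\t{seq}\n")
        with open(outdir / "truth_snps.tsv", "w") as fh:
            fh.write("fragment\toffset\tref\talt\t" + "\t".join(self.genotype_ids) + "\n")
            for j, (fi, off, ref, alt) in enumerate(self.snps):
                states = "\t".join(str(int(s)) for s in self.states[:, j])
                fh.write(f"F{fi:04d}\t{off}\t{ref}\t{alt}\t{states}\n")


@dataclass
class SimResult:
    config: SimulationConfig
    truth: TruthTable
    barcode_table: BarcodeTable
    enzymes: EnzymePair
    r1_path: Optional[Path] = None
    r2_path: Optional[Path] = None
    barcode_path: Optional[Path] = None
    #: read id -> fragment index (provenance of every simulated pair)
    provenance: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def generate_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic 6-10 bp barcode set; same-length barcodes kept at Hamming
    distance >= 3 so one planted error never makes assignment ambiguous."""
    lengths = [6 + (i % 5) for i in range(n)]
    out: list[str] = []
    for L in lengths:
        while True:
            cand = _random_seq(rng, L)
            ok = all(
                sum(a != b for a, b in zip(cand, bc)) >= 3
                for bc in out
                if len(bc) == L
            )
            if ok and cand not in out:
                out.append(cand)
                break
    return out


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in positions:
        old = chars[p]
        choices = [b for b in BASES if b != old] if old in BASES else list(BASES)
        chars[p] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def simulate(config: SimulationConfig, outdir=None, gzip_out: bool = False) -> SimResult:
    """Generate the multiplexed FASTQ pair, barcode file and truth tables.

    With outdir=None nothing is written; the FASTQ stream is still generated
    (deterministically) and provenance recorded.
    """
    rng = np.random.default_rng(config.seed)
    enz = EnzymePair()
    n_total = config.n_genotypes + config.n_replicates
    gids = [f"G{i+1:02d}" for i in range(config.n_genotypes)]
    gids += [f"{gids[0]}rep{i+1}" for i in range(config.n_replicates)]
    barcodes = generate_barcodes(n_total, rng)
    if len(barcodes) < n_total:
        raise ValueError("barcode set smaller than the number of genotypes")
    table = BarcodeTable(list(zip(barcodes, gids)))

    lo, hi = config.fragment_len_range
    frag_lens = rng.integers(lo, hi + 1, size=config.n_fragments)
    fragments = [_random_seq(rng, int(L)) for L in frag_lens]

    # plant bi-allelic SNPs at distinct (fragment, offset) sites
    snps: list[tuple[int, int, str, str]] = []
    used: set[tuple[int, int]] = set()
    while len(snps) < config.n_snps:
        fi = int(rng.integers(0, config.n_fragments))
        off = int(rng.integers(0, len(fragments[fi])))
        if (fi, off) in used:
            continue
        used.add((fi, off))
        ref = fragments[fi][off]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        snps.append((fi, off, ref, alt))
    snps.sort()

    # true genotype states; replicates share the first genotype's states
    if config.n_snps:
        u = rng.random((config.n_genotypes, config.n_snps))
        states = np.where(
            u < config.het_fraction, 1,
            np.where(u < config.het_fraction + (1 - config.het_fraction) / 2, 0, 2),
        ).astype(np.int8)
    else:
        states = np.zeros((config.n_genotypes, 0), dtype=np.int8)
    if config.n_replicates:
        states = np.vstack([states, np.repeat(states[0:1], config.n_replicates, axis=0)])

    truth = TruthTable(fragments, snps, states, gids)
    snps_by_frag: dict[int, list[int]] = {}
    for j, (fi, _, _, _) in enumerate(snps):
        snps_by_frag.setdefault(fi, []).append(j)

    provenance: dict[str, int] = {}
    reads: list[tuple[str, str, str, str, str]] = []  # id, s1, q1, s2, q2
    R = config.read_len
    for gi, gid in enumerate(gids):
        bc = barcodes[gi]
        for fi, frag in enumerate(fragments):
            depth = int(rng.poisson(config.mean_depth))
            if depth == 0:
                continue
            site_idx = snps_by_frag.get(fi, [])
            # resolve hom sites once; het sites are drawn per read
            base_hap = list(frag)
            het_sites = []
            for j in site_idx:
                _, off, ref, alt = snps[j]
                st = states[gi, j]
                if st == 2:
                    base_hap[off] = alt
                elif st == 1:
                    het_sites.append((off, ref, alt))
            base_hap_s = "".join(base_hap)
            for r in range(depth):
                hap = base_hap_s
                if het_sites:
                    chars = list(hap)
                    for off, ref, alt in het_sites:
                        chars[off] = alt if rng.random() < 0.5 else ref
                    hap = "".join(chars)
                t1 = bc + enz.rare_remnant + hap + revcomp(enz.common_remnant) + _ADAPTER_TAIL
                t2 = enz.common_remnant + revcomp(hap) + revcomp(enz.rare_remnant) + revcomp(bc) + _ADAPTER_TAIL
                s1 = _mutate(t1[:R], rng, config.error_rate_per_base)
                s2 = _mutate(t2[:R], rng, config.error_rate_per_base)
                rid = f"SIM_{gid}_F{fi:04d}_{r}"
                provenance[rid] = fi
                reads.append((rid, s1, "I" * R, s2, "I" * R))

    # multiplex: deterministic shuffle across genotypes/fragments
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]

    result = SimResult(config, truth, table, enz, provenance=provenance)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_out else ".fastq"
        result.r1_path = outdir / f"raw.R1{ext}"
        result.r2_path = outdir / f"raw.R2{ext}"
        result.barcode_path = outdir / "barcodes.tsv"
        gio.write_fastq(result.r1_path, ((rid, s1, q1) for rid, s1, q1, _, _ in reads))
        gio.write_fastq(result.r2_path, ((rid, s2, q2) for rid, _, _, s2, q2 in reads))
        table.to_tsv(result.barcode_path)
        truth.write(outdir)
    result.reads = reads  # in-memory access for tests
    return result
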