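"""Stage drivers wiring the pipeline end to end, plus run manifests.

Each stage is runnable independently given its declared inputs (missing
prerequisites raise errors naming the upstream stage); `run_all` composes them
and equals the stepwise composition. All randomness lives in the simulator, so
a fixed input and parameter set reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .fastq_processing import (
    BarcodeTable,
    EnzymePair,
    ParseStats,
    TrimStats,
    demultiplex,
    parse_fastq_pair_files,
    quality_trim,
)
from .mock_reference import (
    MergedRead,
    MockReference,
    build_mock_reference,
    merge_and_stitch,
    select_most_abundant,
)
from .alignment import (
    PileupEngine,
    Reference,
    map_pair,
    read_external_pileup,
    write_pileup,
    write_sam,
)
from .matrices import (
    MasterMatrix,
    build_master_matrix,
    indel_positions,
    pileup_to_counts,
    polymorphic_candidates,
    write_counts,
)
from .variant_calling import CallingParams, SNPRecord, call_snps, write_snp_matrix
from . import io as gio


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, params: dict, inputs: Sequence, seed=None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _require(path, what: str, upstream: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{what} not found at {path}; run the '{upstream}' stage first"
        )
    return path


@dataclass
class Stage1Result:
    demux_paths: dict  # gid -> (R1 path, R2 path)
    singles_path: Path
    parse_stats: ParseStats
    trim_stats: TrimStats
    pairs_per_genotype: dict


def run_stage1(
    r1_path,
    r2_path,
    barcode_path,
    outdir,
    enz: EnzymePair | None = None,
    max_mismatch: int = 1,
    keep_remnant: bool = False,
    require_r2_remnant: bool = False,
    window: int = 4,
    min_q: int = 30,
    lead_q: int = 30,
    trail_q: int = 30,
    min_len: int = 32,
) -> Stage1Result:
    """Parse, quality-trim and demultiplex the raw multiplexed FASTQ pair."""
    enz = enz or EnzymePair()
    _require(r1_path, "raw R1 FASTQ", "simulate")
    _require(r2_path, "raw R2 FASTQ", "simulate")
    table = BarcodeTable.from_tsv(_require(barcode_path, "barcode file", "simulate"))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, pstats = parse_fastq_pair_files(
        r1_path, r2_path, table, enz,
        max_mismatch=max_mismatch,
        keep_remnant=keep_remnant,
        require_r2_remnant=require_r2_remnant,
    )
    counts: dict[str, int] = {g: 0 for g in table.genotype_ids}

    def counting(recs):
        for rec in recs:
            counts[rec[1]] += 1
            yield rec

    paths, singles, tstats = demultiplex(
        counting(records), table, outdir,
        window=window, min_q=min_q, lead_q=lead_q, trail_q=trail_q, min_len=min_len,
    )
    pstats.check()
    pstats.to_tsv(outdir / "parse_stats.tsv")
    with open(outdir / "read_counts.tsv", "w") as fh:
        for g in table.genotype_ids:
            fh.write(f"{g}\t{counts[g]}\n")
    write_manifest(
        outdir, "stage1",
        dict(max_mismatch=max_mismatch, window=window, min_q=min_q,
             lead_q=lead_q, trail_q=trail_q, min_len=min_len),
        [r1_path, r2_path, barcode_path],
    )
    return Stage1Result(paths, singles, pstats, tstats, counts)


def read_demuxed_pairs(r1_path, r2_path):
    """Yield (read_id, (seq1, qual1), (seq2, qual2)) from a demuxed file pair."""
    for (t1, s1, q1), (t2, s2, q2) in zip(gio.read_fastq(r1_path), gio.read_fastq(r2_path)):
        yield t1.split()[0], (s1, q1), (s2, q2)


def run_mockref(
    demux_paths: dict,
    outdir,
    selected: Sequence[str] | int = 1,
    threshold: float = 0.93,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_len: int = 32,
    pairs_per_genotype: Optional[dict] = None,
) -> tuple[MockReference, dict[str, list[MergedRead]]]:
    """Merge/stitch the selected genotypes' reads and cluster the mock reference.

    `selected` is either an explicit genotype list or an integer n meaning the
    n most read-abundant genotypes (by parsed-read count).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(selected, int):
        if pairs_per_genotype is None:
            pairs_per_genotype = {
                g: sum(1 for _ in gio.read_fastq(p1)) for g, (p1, _) in demux_paths.items()
            }
        selected = select_most_abundant(pairs_per_genotype, selected)
    per_geno: dict[str, list[MergedRead]] = {}
    for gid in selected:
        if gid not in demux_paths:
            raise KeyError(f"no demultiplexed files for genotype {gid!r}; run 'parse' first")
        p1, p2 = demux_paths[gid]
        _require(p1, f"{gid} R1", "parse")
        _require(p2, f"{gid} R2", "parse")
        per_geno[gid] = merge_and_stitch(
            read_demuxed_pairs(p1, p2), min_overlap, max_mismatch_frac, min_len
        )
    mock = build_mock_reference(per_geno, list(selected), threshold)
    mock.write_fasta(outdir / "MockRef_Genome.fasta", outdir / "MockRef_Clusters.fasta")
    mock.write_membership(outdir / "MockRef_Membership.tsv")
    write_manifest(
        outdir, "mockref",
        dict(selected=list(selected), threshold=threshold, min_overlap=min_overlap,
             max_mismatch_frac=max_mismatch_frac, min_len=min_len),
        [p for gid in selected for p in demux_paths[gid]],
    )
    return mock, per_geno


def align_genotype(
    r1_path,
    r2_path,
    ref: Reference,
    max_edit_frac: float = 0.07,
    min_base_q: int = 0,
    sam_path=None,
) -> PileupEngine:
    """Map one genotype's pairs and accumulate its pileup."""
    engine = PileupEngine(ref, min_base_q=min_base_q)
    sam_pairs = [] if sam_path else None
    for rid, r1, r2 in read_demuxed_pairs(r1_path, r2_path):
        pair = map_pair(r1, r2, ref, max_edit_frac, read_id=rid)
        if pair is None:
            continue
        engine.add_pair(pair)
        if sam_pairs is not None:
            sam_pairs.append(pair)
    if sam_path:
        write_sam(sam_pairs, ref, sam_path)
    return engine


def run_align_all(
    demux_paths: dict,
    ref: Reference,
    outdir=None,
    max_edit_frac: float = 0.07,
    min_base_q: int = 0,
    write_pileups: bool = True,
) -> dict[str, PileupEngine]:
    """Map every genotype against the reference; optionally write mpileup text."""
    engines = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for gid, (p1, p2) in demux_paths.items():
        engines[gid] = align_genotype(p1, p2, ref, max_edit_frac, min_base_q)
        if outdir is not None and write_pileups:
            write_pileup(engines[gid].columns(), outdir / f"{gid}.mpileup.txt")
    return engines


def run_master_matrix(
    per_genotype_columns: dict,
    outdir=None,
    genotype_order: Sequence[str] | None = None,
) -> MasterMatrix:
    """Counts + candidates + master matrix from per-genotype pileup columns."""
    gids = list(genotype_order) if genotype_order else list(per_genotype_columns)
    counts, cands, indels = {}, {}, {}
    for gid in gids:
        cols = per_genotype_columns[gid]
        counts[gid] = pileup_to_counts(cols)
        cands[gid] = polymorphic_candidates(counts[gid])
        indels[gid] = indel_positions(cols)
        if outdir is not None:
            write_counts(counts[gid], Path(outdir) / f"{gid}.counts.tsv")
    master = build_master_matrix(counts, cands, indels, genotype_order=gids)
    if outdir is not None:
        master.to_tsv(Path(outdir) / "master_matrix.tsv")
    return master


def run_callsnps(
    master: MasterMatrix,
    params: CallingParams | None = None,
    out_path=None,
) -> list[SNPRecord]:
    records = call_snps(master, params or CallingParams())
    if out_path is not None:
        write_snp_matrix(records, master.genotype_ids, out_path)
    return records


@dataclass
class PipelineResult:
    stage1: Stage1Result
    mock: MockReference
    merged: dict  # gid -> list[MergedRead] for selected genotypes
    reference: Reference
    engines: dict  # gid -> PileupEngine
    master: MasterMatrix
    records: list
    params: CallingParams


def run_all(
    r1_path,
    r2_path,
    barcode_path,
    workdir,
    selected: Sequence[str] | int = 1,
    cluster_threshold: float = 0.93,
    max_edit_frac: float = 0.07,
    params: CallingParams | None = None,
    write_pileups: bool = False,
) -> PipelineResult:
    """Full reference-free pipeline: raw FASTQ pair -> final SNP matrix."""
    workdir = Path(workdir)
    params = params or CallingParams()
    stage1 = run_stage1(r1_path, r2_path, barcode_path, workdir / "demux")
    mock, merged = run_mockref(
        stage1.demux_paths, workdir / "mockref", selected=selected,
        threshold=cluster_threshold, pairs_per_genotype=stage1.pairs_per_genotype,
    )
    ref = Reference.from_mock(mock)
    engines = run_align_all(
        stage1.demux_paths, ref,
        outdir=(workdir / "pileups") if write_pileups else None,
        max_edit_frac=max_edit_frac,
    )
    gids = [g for g in stage1.pairs_per_genotype]
    outdir = workdir / "matrices"
    outdir.mkdir(parents=True, exist_ok=True)
    # stream one genotype's pileup columns at a time to keep memory flat
    counts, cands, indels = {}, {}, {}
    for g in gids:
        cols = engines[g].columns()
        counts[g] = pileup_to_counts(cols)
        cands[g] = polymorphic_candidates(counts[g])
        indels[g] = indel_positions(cols)
        write_counts(counts[g], outdir / f"{g}.counts.tsv")
    master = build_master_matrix(counts, cands, indels, genotype_order=gids)
    master.to_tsv(outdir / "master_matrix.tsv")
    records = run_callsnps(master, params, outdir / "snp_matrix.tsv")
    return PipelineResult(stage1, mock, merged, ref, engines, master, records, params)
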