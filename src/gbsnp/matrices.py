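"""Step 6: count files, candidate SNP positions and the population master matrix.

Per-genotype pileups are distilled into count rows (ref_id, pos, ref_base,
A/C/G/T depths) with every indel-bearing position excluded; positions carrying
any read polymorphic to the reference form a liberal per-genotype candidate
list, and the union of candidates over all genotypes — with each genotype's
full depth 4-tuple filled in whether or not it was itself polymorphic there —
is the master matrix. A position with indel evidence in any genotype is
removed population-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dna import BASE_INDEX, BASES
from .alignment import PileupColumn
from . import io as gio


@dataclass(frozen=True)
class CountRow:
    ref_id: str
    pos: int  # 1-based
    ref_base: str
    depths: tuple[int, int, int, int]


def pileup_to_counts(cols: Iterable[PileupColumn]) -> list[CountRow]:
    """One CountRow per covered, indel-free position; indel positions dropped."""
    out = []
    for c in cols:
        if c.indel_evidence:
            continue
        if sum(c.depths) == 0:
            continue
        out.append(CountRow(c.ref_id, c.pos, c.ref_base, tuple(c.depths)))
    return out


def indel_positions(cols: Iterable[PileupColumn]) -> set[tuple[str, int]]:
    return {(c.ref_id, c.pos) for c in cols if c.indel_evidence}


def polymorphic_candidates(rows: Iterable[CountRow]) -> list[tuple[str, int]]:
    """Positions where any read disagrees with the reference base (depth-free,
    deliberately liberal at this stage)."""
    out = []
    for r in rows:
        ref_i = BASE_INDEX.get(r.ref_base)
        nonref = sum(d for i, d in enumerate(r.depths) if i != ref_i)
        if nonref > 0:
            out.append((r.ref_id, r.pos))
    return out


def write_counts(rows: Iterable[CountRow], path) -> None:
    with gio.open_text(path, "wt") as fh:
        for r in rows:
            fh.write(f"{r.ref_id}\t{r.pos}\t{r.ref_base}\t" + ",".join(map(str, r.depths)) + "\n")


def read_counts(path) -> list[CountRow]:
    rows = []
    with gio.open_text(path) as fh:
        for line in fh:
            ref_id, pos, base, depths = line.rstrip("\n").split("\t")
            rows.append(CountRow(ref_id, int(pos), base, tuple(int(x) for x in depths.split(","))))
    return rows


class MasterMatrix:
    """Population depth table: positions x genotypes x (A,C,G,T)."""

    def __init__(
        self,
        positions: Sequence[tuple[str, int, str]],
        genotype_ids: Sequence[str],
        depths: np.ndarray,
    ):
        self.positions = list(positions)
        self.genotype_ids = list(genotype_ids)
        self.depths = np.asarray(depths, dtype=np.int64)
        if self.depths.shape != (len(self.positions), len(self.genotype_ids), 4):
            raise ValueError("depth array shape does not match positions/genotypes")
        if (self.depths < 0).any():
            raise ValueError("negative depths")

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self, path) -> None:
        with gio.open_text(path, "wt") as fh:
            fh.write("ref_id\tpos\tref_base\t" + "\t".join(self.genotype_ids) + "\n")
            for i, (ref_id, pos, base) in enumerate(self.positions):
                cells = [",".join(map(str, self.depths[i, g])) for g in range(len(self.genotype_ids))]
                fh.write(f"{ref_id}\t{pos}\t{base}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MasterMatrix":
        with gio.open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            gids = header[3:]
            positions, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                positions.append((parts[0], int(parts[1]), parts[2]))
                rows.append([[int(x) for x in cell.split(",")] for cell in parts[3:]])
        depths = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, len(gids), 4), dtype=np.int64)
        return cls(positions, gids, depths)


def build_master_matrix(
    per_genotype_counts: dict[str, Sequence[CountRow]],
    per_genotype_candidates: dict[str, Sequence[tuple[str, int]]] | None = None,
    per_genotype_indels: dict[str, Iterable[tuple[str, int]]] | None = None,
    genotype_order: Sequence[str] | None = None,
) -> MasterMatrix:
    """Assemble the population master matrix.

    The position set is the deduplicated, (ref_id, pos)-sorted union of the
    per-genotype candidate lists (computed from the counts when not supplied);
    each cell holds that genotype's full depth 4-tuple at the position, zero
    when uncovered. Positions with indel evidence in any genotype are excluded
    population-wide. Conflicting reference bases across genotypes are a hard
    error.
    """
    gids = list(genotype_order) if genotype_order is not None else list(per_genotype_counts)
    if per_genotype_candidates is None:
        per_genotype_candidates = {
            g: polymorphic_candidates(per_genotype_counts[g]) for g in gids
        }
    banned: set[tuple[str, int]] = set()
    if per_genotype_indels:
        for g in gids:
            banned |= set(per_genotype_indels.get(g, ()))
    union: set[tuple[str, int]] = set()
    for g in gids:
        union |= set(per_genotype_candidates.get(g, ()))
    union -= banned
    keys = sorted(union)

    ref_base: dict[tuple[str, int], str] = {}
    for g in gids:
        for r in per_genotype_counts[g]:
            k = (r.ref_id, r.pos)
            prev = ref_base.get(k)
            if prev is None:
                ref_base[k] = r.ref_base
            elif prev != r.ref_base:
                raise ValueError(
                    f"inconsistent reference base at {k}: {prev} vs {r.ref_base} (genotype {g})"
                )

    idx = {k: i for i, k in enumerate(keys)}
    depths = np.zeros((len(keys), len(gids), 4), dtype=np.int64)
    for gi, g in enumerate(gids):
        for r in per_genotype_counts[g]:
            i = idx.get((r.ref_id, r.pos))
            if i is not None:
                depths[i, gi] = r.depths
    positions = [(k[0], k[1], ref_base.get(k, "N")) for k in keys]
    return MasterMatrix(positions, gids, depths)
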