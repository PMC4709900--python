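"""Step 7: SNP culling filters, depth-based genotype calls and the final matrix.

A master-matrix row survives as a SNP when (1) the putative secondary allele is
seen independently, at a minimum depth (default 3), in at least three
genotypes; (2) it is strongly bi-allelic, i.e. the secondary allele's share of
the non-primary population depth, 2°/(2°+3°+4°), strictly exceeds altStrength
(default 0.90); and (3) after per-genotype genotyping, at least 75% of
genotypes are scored and the population average depth lies strictly between 4
and 200. Genotypes are assigned from the genotype's depths of the row's
primary/secondary alleles: a heterozygote needs both alleles at depth >= 3 and
a low/high depth ratio strictly above 0.1; a homozygote needs depth >= 11 when
the other allele's count is 0 or >= 48 when it is 1; anything else is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dna import BASES
from .matrices import MasterMatrix
from . import io as gio

HOM_PRIMARY = "hom_primary"
HET = "het"
HOM_SECONDARY = "hom_secondary"
MISSING = "missing"

_STATE_TOKEN = {HOM_PRIMARY: "P", HET: "H", HOM_SECONDARY: "S", MISSING: "-"}
_TOKEN_STATE = {v: k for k, v in _STATE_TOKEN.items()}


@dataclass(frozen=True)
class CallingParams:
    indep_min_depth: int = 3
    indep_min_genotypes: int = 3
    alt_strength: float = 0.90
    het_min_each: int = 3
    het_min_ratio: float = 0.1
    homo_min_depth_alt0: int = 11
    homo_min_depth_alt1: int = 48
    min_called_frac: float = 0.75
    min_avg_depth: float = 4  # cull avg depth <= this
    max_avg_depth: float = 200  # cull avg depth >= this
    avg_depth_over_covered_only: bool = False

    def __post_init__(self):
        for name in ("alt_strength", "het_min_ratio", "min_called_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "indep_min_depth", "indep_min_genotypes", "het_min_each",
            "homo_min_depth_alt0", "homo_min_depth_alt1",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AlleleRanking:
    """Bases ordered by population-summed depth; ties broken A<C<G<T."""

    bases: tuple[str, str, str, str]  # primary..quaternary
    depths: tuple[int, int, int, int]

    @property
    def primary(self) -> str:
        return self.bases[0]

    @property
    def secondary(self) -> str:
        return self.bases[1]


@dataclass(frozen=True)
class GenotypeCall:
    state: str
    primary_depth: int
    secondary_depth: int

    def __str__(self) -> str:
        return f"{_STATE_TOKEN[self.state]}|{self.primary_depth}/{self.secondary_depth}"

    @classmethod
    def from_str(cls, s: str) -> "GenotypeCall":
        tok, rest = s.split("|")
        p, sec = rest.split("/")
        return cls(_TOKEN_STATE[tok], int(p), int(sec))


@dataclass
class SNPRecord:
    ref_id: str
    pos: int
    ref_base: str
    avg_depth: float
    primary_allele: str
    secondary_allele: str
    pct_genotyped: float  # 0-100
    n_hom_primary: int
    n_het: int
    n_hom_secondary: int
    calls: list[GenotypeCall] = field(default_factory=list)


def rank_alleles(pop_depths: Sequence[int]) -> AlleleRanking:
    """Order A/C/G/T by total population depth, ties broken by base order."""
    order = sorted(range(4), key=lambda i: (-int(pop_depths[i]), i))
    return AlleleRanking(
        bases=tuple(BASES[i] for i in order),
        depths=tuple(int(pop_depths[i]) for i in order),
    )


def independence_filter(
    genotype_depths: np.ndarray, ranking: AlleleRanking, params: CallingParams
) -> bool:
    """Pass iff >= indep_min_genotypes genotypes each carry the secondary
    allele at depth >= indep_min_depth."""
    sec_i = BASES.index(ranking.secondary)
    n = int((np.asarray(genotype_depths)[:, sec_i] >= params.indep_min_depth).sum())
    return n >= params.indep_min_genotypes


def alt_strength_filter(ranking: AlleleRanking, params: CallingParams) -> bool:
    """Strong bi-allelism: 2°depth / (2°+3°+4° depth) > alt_strength (strict)."""
    denom = sum(ranking.depths[1:])
    if denom == 0:
        return False  # no non-primary reads at all: monomorphic, not a SNP
    return ranking.depths[1] / denom > params.alt_strength


def call_genotype(
    primary_depth: int, secondary_depth: int, params: CallingParams | None = None
) -> GenotypeCall:
    """Assign a genotypic state from one genotype's primary/secondary depths."""
    if params is None:
        params = CallingParams()
    p, s = int(primary_depth), int(secondary_depth)
    state = MISSING
    if p >= params.het_min_each and s >= params.het_min_each:
        lo, hi = (p, s) if p <= s else (s, p)
        if hi > 0 and lo > params.het_min_ratio * hi:
            state = HET
    if state == MISSING:
        if s == 0 and p >= params.homo_min_depth_alt0:
            state = HOM_PRIMARY
        elif s == 1 and p >= params.homo_min_depth_alt1:
            state = HOM_PRIMARY
        elif p == 0 and s >= params.homo_min_depth_alt0:
            state = HOM_SECONDARY
        elif p == 1 and s >= params.homo_min_depth_alt1:
            state = HOM_SECONDARY
    return GenotypeCall(state, p, s)


def population_filters(
    records: Iterable[SNPRecord], params: CallingParams | None = None
) -> list[SNPRecord]:
    """Retain records with >= min_called_frac scored genotypes and average
    depth strictly between min_avg_depth and max_avg_depth."""
    if params is None:
        params = CallingParams()
    out = []
    for r in records:
        if r.pct_genotyped / 100.0 < params.min_called_frac:
            continue
        if not (params.min_avg_depth < r.avg_depth < params.max_avg_depth):
            continue
        out.append(r)
    return out


def call_snps(master: MasterMatrix, params: CallingParams | None = None) -> list[SNPRecord]:
    """Run the full SNP-calling cascade over a master matrix.

    Pipeline order: allele ranking -> independence filter -> altStrength
    filter -> per-genotype genotype calls -> population filters. Fully
    deterministic for a given matrix and parameter set.
    """
    if params is None:
        params = CallingParams()
    n_pos = len(master)
    if n_pos == 0:
        return []
    depths = master.depths  # (P, G, 4)
    n_gt = depths.shape[1]
    pop = depths.sum(axis=1)  # (P, 4)

    # vectorised allele ranking with A<C<G<T tie-break: sort on (-depth, base index)
    order = np.argsort(pop * 4 - np.arange(4), axis=1, kind="stable")[:, ::-1]
    ranked = np.take_along_axis(pop, order, axis=1)  # (P, 4) descending
    sec_base_idx = order[:, 1]

    # independence: per-genotype depth of the secondary allele
    sec_depth = np.take_along_axis(
        depths, sec_base_idx[:, None, None].repeat(n_gt, axis=1), axis=2
    )[:, :, 0]
    indep_ok = (sec_depth >= params.indep_min_depth).sum(axis=1) >= params.indep_min_genotypes

    denom = ranked[:, 1:].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        strength = np.where(denom > 0, ranked[:, 1] / np.maximum(denom, 1), 0.0)
    alt_ok = (denom > 0) & (strength > params.alt_strength)

    keep = np.flatnonzero(indep_ok & alt_ok & (ranked[:, 1] > 0))
    if keep.size == 0:
        return []

    pri_idx = order[keep, 0]
    sec_idx = order[keep, 1]
    d = depths[keep]  # (K, G, 4)
    K = keep.size
    p_dep = d[np.arange(K)[:, None], np.arange(n_gt)[None, :], pri_idx[:, None]]
    s_dep = d[np.arange(K)[:, None], np.arange(n_gt)[None, :], sec_idx[:, None]]

    lo = np.minimum(p_dep, s_dep)
    hi = np.maximum(p_dep, s_dep)
    het = (
        (p_dep >= params.het_min_each)
        & (s_dep >= params.het_min_each)
        & (lo > params.het_min_ratio * hi)
    )
    hom_p = ~het & (
        ((s_dep == 0) & (p_dep >= params.homo_min_depth_alt0))
        | ((s_dep == 1) & (p_dep >= params.homo_min_depth_alt1))
    )
    hom_s = ~het & ~hom_p & (
        ((p_dep == 0) & (s_dep >= params.homo_min_depth_alt0))
        | ((p_dep == 1) & (s_dep >= params.homo_min_depth_alt1))
    )
    called = het | hom_p | hom_s

    if params.avg_depth_over_covered_only:
        tot = d.sum(axis=2)
        cov = (tot > 0).sum(axis=1)
        avg = np.where(cov > 0, tot.sum(axis=1) / np.maximum(cov, 1), 0.0)
    else:
        avg = d.sum(axis=(1, 2)) / n_gt

    records = []
    for k in range(K):
        i = keep[k]
        ref_id, pos, ref_base = master.positions[i]
        calls = []
        for g in range(n_gt):
            if het[k, g]:
                state = HET
            elif hom_p[k, g]:
                state = HOM_PRIMARY
            elif hom_s[k, g]:
                state = HOM_SECONDARY
            else:
                state = MISSING
            calls.append(GenotypeCall(state, int(p_dep[k, g]), int(s_dep[k, g])))
        rec = SNPRecord(
            ref_id=ref_id,
            pos=pos,
            ref_base=ref_base,
            avg_depth=float(avg[k]),
            primary_allele=BASES[pri_idx[k]],
            secondary_allele=BASES[sec_idx[k]],
            pct_genotyped=100.0 * int(called[k].sum()) / n_gt,
            n_hom_primary=int(hom_p[k].sum()),
            n_het=int(het[k].sum()),
            n_hom_secondary=int(hom_s[k].sum()),
            calls=calls,
        )
        records.append(rec)
    return population_filters(records, params)


def write_snp_matrix(records: Iterable[SNPRecord], genotype_ids: Sequence[str], path) -> None:
    """Final genotyping matrix: 10 summary columns then one call per genotype
    formatted 'state|primary/secondary' with '-' marking missing."""
    with gio.open_text(path, "wt") as fh:
        header = [
            "ref_id", "pos", "ref_base", "avg_depth", "primary_allele",
            "secondary_allele", "pct_genotyped", "n_hom_primary", "n_het",
            "n_hom_secondary",
        ] + list(genotype_ids)
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [
                r.ref_id, str(r.pos), r.ref_base, f"{r.avg_depth:.2f}",
                r.primary_allele, r.secondary_allele, f"{r.pct_genotyped:.2f}",
                str(r.n_hom_primary), str(r.n_het), str(r.n_hom_secondary),
            ] + [str(c) for c in r.calls]
            fh.write("\t".join(row) + "\n")


def read_snp_matrix(path) -> tuple[list[SNPRecord], list[str]]:
    records = []
    with gio.open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gids = header[10:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            records.append(
                SNPRecord(
                    ref_id=parts[0], pos=int(parts[1]), ref_base=parts[2],
                    avg_depth=float(parts[3]), primary_allele=parts[4],
                    secondary_allele=parts[5], pct_genotyped=float(parts[6]),
                    n_hom_primary=int(parts[7]), n_het=int(parts[8]),
                    n_hom_secondary=int(parts[9]),
                    calls=[GenotypeCall.from_str(c) for c in parts[10:]],
                )
            )
    return records, gids
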