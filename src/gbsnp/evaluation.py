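"""Score a reference-free pipeline run against the simulator's truth tables.

Translates planted SNP coordinates (fragment, offset) onto mock-reference
centroid coordinates via the provenance of each centroid's founding read, then
measures planted-SNP recovery, per-genotype state concordance and false-SNP
counts. A planted SNP is *design-eligible* when its position is observable
under the library design: on a merged (assembled) centroid anywhere, on a
stitched centroid only within the R1/R2-covered flanks (the un-sequenced
fragment middle cannot be genotyped by any method).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .mock_reference import MergedRead, MockReference
from .pipeline import PipelineResult
from .synthetic_data import SimResult
from .variant_calling import HET, HOM_PRIMARY, HOM_SECONDARY, MISSING, SNPRecord


def _centroid_provenance(result: PipelineResult, sim: SimResult):
    """fragment index -> (centroid_id, MergedRead of the founding read)."""
    merged_by_id: dict[str, MergedRead] = {}
    for reads in result.merged.values():
        for m in reads:
            merged_by_id[m.id] = m
    frag_to_centroid: dict[int, tuple[str, MergedRead]] = {}
    for c in result.mock.centroids:
        founder = merged_by_id[c.members[0]]
        fi = sim.provenance.get(founder.id)
        if fi is not None and fi not in frag_to_centroid:
            frag_to_centroid[fi] = (c.id, founder)
    return frag_to_centroid


def _local_position(founder: MergedRead, frag_len: int, offset: int) -> Optional[int]:
    """1-based centroid-local position of a fragment offset, or None if the
    offset is not represented on the centroid."""
    if founder.origin == "assembled":
        if len(founder.seq) != frag_len:
            return None  # founder carried an indel-like artifact; skip
        return offset + 1
    l1 = founder.r1_len or 0
    l2 = len(founder.seq) - l1 - 20
    if offset < l1:
        return offset + 1
    if offset >= frag_len - l2:
        return l1 + 20 + (offset - (frag_len - l2)) + 1
    return None


@dataclass
class TruthEvaluation:
    n_planted: int
    n_eligible: int
    n_recovered: int
    n_called_snps: int
    n_false_snps: int
    n_concordant_calls: int
    n_compared_calls: int
    recovered: list = field(default_factory=list)

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_eligible if self.n_eligible else 0.0

    @property
    def concordance_pct(self) -> float:
        return (
            100.0 * self.n_concordant_calls / self.n_compared_calls
            if self.n_compared_calls
            else 0.0
        )


_STATE_OF_TRUTH = {0: "ref", 1: "het", 2: "alt"}


def evaluate_against_truth(result: PipelineResult, sim: SimResult) -> TruthEvaluation:
    """Compare called SNPs and genotype states with the planted truth."""
    cfg = sim.config
    max_bc = max(len(bc) for bc, _ in sim.barcode_table.entries)
    r1_cov = cfg.read_len - max_bc - len(sim.enzymes.rare_remnant)
    r2_cov = cfg.read_len - len(sim.enzymes.common_remnant)

    frag_to_centroid = _centroid_provenance(result, sim)
    called = {(r.ref_id, r.pos): r for r in result.records}
    gids = result.master.genotype_ids
    truth_gids = sim.truth.genotype_ids
    gidx = {g: i for i, g in enumerate(truth_gids)}

    min_carriers = result.params.indep_min_genotypes
    expected_keys = set()
    n_eligible = n_recovered = 0
    n_concordant = n_compared = 0
    recovered = []
    for j, (fi, off, ref, alt) in enumerate(sim.truth.snps):
        frag_len = len(sim.truth.fragments[fi])
        entry = frag_to_centroid.get(fi)
        if entry is None:
            continue  # fragment never made it into the mock reference
        cid, founder = entry
        local = _local_position(founder, frag_len, off)
        if local is None:
            continue
        # observable by every genotype regardless of barcode length?
        if off >= r1_cov and off < frag_len - r2_cov:
            continue
        # the independence filter demands the minor allele in >= 3 genotypes:
        # a SNP whose truth has fewer carriers of either allele is culled by design
        col = sim.truth.states[:, j]
        alt_carriers = int((col >= 1).sum())
        ref_carriers = int((col <= 1).sum())
        if min(alt_carriers, ref_carriers) < min_carriers:
            continue
        n_eligible += 1
        key = (cid, local)
        expected_keys.add(key)
        rec = called.get(key)
        if rec is None or {rec.primary_allele, rec.secondary_allele} != {ref, alt}:
            continue
        n_recovered += 1
        recovered.append((j, rec))
        # state concordance over non-missing calls
        pri_is_ref = rec.primary_allele == ref
        for g, call in zip(gids, rec.calls):
            if call.state == MISSING or g not in gidx:
                continue
            truth_state = int(sim.truth.states[gidx[g], j])
            if call.state == HET:
                ok = truth_state == 1
            elif call.state == HOM_PRIMARY:
                ok = truth_state == (0 if pri_is_ref else 2)
            else:
                ok = truth_state == (2 if pri_is_ref else 0)
            n_compared += 1
            n_concordant += int(ok)

    # false SNPs: called positions not corresponding to any planted SNP site
    planted_keys = set()
    for j, (fi, off, ref, alt) in enumerate(sim.truth.snps):
        entry = frag_to_centroid.get(fi)
        if entry is None:
            continue
        local = _local_position(entry[1], len(sim.truth.fragments[fi]), off)
        if local is not None:
            planted_keys.add((entry[0], local))
    n_false = sum(1 for k in called if k not in planted_keys)

    return TruthEvaluation(
        n_planted=len(sim.truth.snps),
        n_eligible=n_eligible,
        n_recovered=n_recovered,
        n_called_snps=len(result.records),
        n_false_snps=n_false,
        n_concordant_calls=n_concordant,
        n_compared_calls=n_compared,
        recovered=recovered,
    )
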