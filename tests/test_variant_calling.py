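"""Step 7: SNP filters, depth-based genotype calls, population culls."""

import numpy as np
import pytest

from gbsnp.matrices import MasterMatrix
from gbsnp.variant_calling import (
    HET,
    HOM_PRIMARY,
    HOM_SECONDARY,
    MISSING,
    AlleleRanking,
    CallingParams,
    GenotypeCall,
    SNPRecord,
    alt_strength_filter,
    call_genotype,
    call_snps,
    independence_filter,
    population_filters,
    rank_alleles,
)

P = CallingParams()


def oracle_call(p, s, params=P):
    """Independently coded genotyping rule table.

    A heterozygote needs both alleles at depth >= 3 with minor/major ratio
    strictly above 0.1; a homozygote needs depth >= 11 against 0 reads of the
    other allele, or >= 48 against exactly 1; everything else is missing.
    """
    if p >= params.het_min_each and s >= params.het_min_each:
        if min(p, s) / max(p, s) > params.het_min_ratio:
            return HET
    for own, other, label in ((p, s, HOM_PRIMARY), (s, p, HOM_SECONDARY)):
        if other == 0 and own >= params.homo_min_depth_alt0:
            return label
        if other == 1 and own >= params.homo_min_depth_alt1:
            return label
    return MISSING


class TestRankAlleles:
    def test_descending_order(self):
        r = rank_alleles((5, 80, 12, 0))
        assert r.bases == ("C", "G", "A", "T")
        assert r.depths == (80, 12, 5, 0)

    def test_tie_broken_by_base_order(self):
        r = rank_alleles((10, 10, 10, 10))
        assert r.bases == ("A", "C", "G", "T")


class TestIndependenceFilter:
    def _depths(self, sec_counts):
        # genotypes x 4, secondary allele = C
        return np.array([[50, c, 0, 0] for c in sec_counts])

    def test_three_genotypes_at_depth_pass(self):
        r = rank_alleles((150, 9, 0, 0))
        assert independence_filter(self._depths([3, 3, 3]), r, P)

    def test_two_genotypes_fail(self):
        r = rank_alleles((100, 6, 0, 0))
        assert not independence_filter(self._depths([3, 3, 0]), r, P)

    def test_depth_two_in_many_genotypes_fails(self):
        r = rank_alleles((500, 20, 0, 0))
        assert not independence_filter(self._depths([2] * 10), r, P)


class TestAltStrengthFilter:
    def _ranking(self, d2, d3, d4, d1=1000):
        return AlleleRanking(("A", "C", "G", "T"), (d1, d2, d3, d4))

    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((95, 5, 0), True),  # 0.95 > 0.90
            ((9, 1, 0), False),  # exactly 0.90: strict inequality fails
            ((10, 0, 0), True),  # 1.0
            ((0, 0, 0), False),  # no secondary allele at all
        ],
    )
    def test_boundary_cases(self, triple, expected):
        assert alt_strength_filter(self._ranking(*triple), P) is expected

    def test_matches_direct_formula_on_random_triples(self):
        rng = np.random.default_rng(50)
        for _ in range(2000):
            d = sorted(rng.integers(0, 300, size=3))[::-1]
            r = self._ranking(*d)
            denom = sum(d)
            expected = denom > 0 and d[0] / denom > 0.90
            assert alt_strength_filter(r, P) is expected


class TestCallGenotype:
    @pytest.mark.parametrize(
        "p,s,state",
        [
            (132, 5, MISSING),  # ratio 5/132 below 0.1
            (0, 4, MISSING),  # secondary homozygote below depth 11
            (11, 0, HOM_PRIMARY),
            (10, 0, MISSING),
            (48, 1, HOM_PRIMARY),
            (47, 1, MISSING),
            (0, 11, HOM_SECONDARY),
            (1, 48, HOM_SECONDARY),
            (20, 10, HET),  # 0.5 ratio, both >= 3
            (3, 3, HET),
            (30, 3, MISSING),  # ratio exactly 0.1 is not enough
            (0, 0, MISSING),
        ],
    )
    def test_rule_boundaries(self, p, s, state):
        assert call_genotype(p, s).state == state

    def test_exhaustive_grid_matches_oracle(self):
        for p in range(61):
            for s in range(61):
                assert call_genotype(p, s).state == oracle_call(p, s), (p, s)

    def test_call_carries_depths(self):
        c = call_genotype(20, 10)
        assert (c.primary_depth, c.secondary_depth) == (20, 10)
        assert str(c) == "H|20/10"
        assert GenotypeCall.from_str(str(c)) == c


def _record(avg_depth=50.0, pct=90.0):
    return SNPRecord("c1", 1, "A", avg_depth, "A", "C", pct, 5, 3, 2, [])


class TestPopulationFilters:
    def test_low_scoring_fraction_culled(self):
        # 35 of 48 genotypes called = 72.9% < 75%
        rec = _record(pct=100 * 35 / 48)
        assert population_filters([rec]) == []

    @pytest.mark.parametrize("avg,kept", [(4, False), (4.01, True), (199.9, True), (200, False), (70, True)])
    def test_depth_bounds_strict(self, avg, kept):
        rec = _record(avg_depth=avg)
        assert (population_filters([rec]) == [rec]) is kept

    def test_empty_input(self):
        assert population_filters([]) == []


def _master(depth_cells, ref_bases=None):
    """depth_cells: positions x genotypes x 4 nested list."""
    arr = np.asarray(depth_cells)
    n_pos, n_gt = arr.shape[0], arr.shape[1]
    positions = [("c1", i + 1, (ref_bases or "A" * n_pos)[i]) for i in range(n_pos)]
    return MasterMatrix(positions, [f"g{j}" for j in range(n_gt)], arr)


class TestCallSnps:
    def _biallelic_master(self, n_gt=6):
        # one clean planted SNP: A primary, C secondary, three het genotypes
        cells = [[[30, 0, 0, 0]] * 3 + [[20, 15, 0, 0]] * 3]
        return _master(cells)

    def test_planted_snp_called_with_correct_alleles(self):
        records = call_snps(self._biallelic_master())
        assert len(records) == 1
        r = records[0]
        assert (r.primary_allele, r.secondary_allele) == ("A", "C")
        assert r.n_hom_primary == 3 and r.n_het == 3 and r.n_hom_secondary == 0
        assert r.pct_genotyped == 100.0

    def test_triallelic_site_removed_by_alt_strength(self):
        # tertiary depth is 20% of the non-primary pool -> fails 0.90
        cells = [[[40, 8, 2, 0]] * 6]
        assert call_snps(_master(cells)) == []

    def test_independence_blocks_single_genotype_variant(self):
        cells = [[[30, 15, 0, 0]] + [[30, 0, 0, 0]] * 5]
        assert call_snps(_master(cells)) == []

    def test_avg_depth_is_mean_over_all_genotypes(self):
        cells = [[[30, 0, 0, 0]] * 3 + [[20, 15, 0, 0]] * 3 + [[0, 0, 0, 0]] * 2]
        records = call_snps(_master(cells))
        assert len(records) == 1
        assert records[0].avg_depth == pytest.approx((30 * 3 + 35 * 3) / 8)

    def test_summary_columns_recount_from_calls(self):
        records = call_snps(self._biallelic_master())
        for r in records:
            states = [c.state for c in r.calls]
            assert r.n_hom_primary == states.count(HOM_PRIMARY)
            assert r.n_het == states.count(HET)
            assert r.n_hom_secondary == states.count(HOM_SECONDARY)
            n_called = len(states) - states.count(MISSING)
            assert r.pct_genotyped == pytest.approx(100 * n_called / len(states))

    def test_determinism(self):
        m = self._biallelic_master()
        a = call_snps(m)
        b = call_snps(m)
        assert a == b

    def test_empty_master(self):
        assert call_snps(_master(np.zeros((0, 4, 4)))) == []

    def test_vectorised_calls_match_scalar_rule(self):
        """The vectorised genotyper inside call_snps must agree with the
        scalar call_genotype on every cell of a random master matrix."""
        rng = np.random.default_rng(51)
        cells = rng.integers(0, 60, size=(40, 8, 4))
        # make most rows plausibly bi-allelic: zero out two bases
        cells[:, :, 2:] //= 8
        m = _master(cells.tolist())
        params = CallingParams(min_called_frac=0.0, min_avg_depth=0, max_avg_depth=10**9)
        records = call_snps(m, params)
        pos_idx = {p[1]: i for i, p in enumerate(m.positions)}
        from gbsnp.dna import BASES

        for r in records:
            i = pos_idx[r.pos]
            pi, si = BASES.index(r.primary_allele), BASES.index(r.secondary_allele)
            for g, call in enumerate(r.calls):
                expect = call_genotype(int(cells[i, g, pi]), int(cells[i, g, si]), params)
                assert call == expect

    def test_filter_monotonicity(self):
        """Raising alt_strength, indep_min_depth or min_called_frac never
        increases the number of retained SNPs."""
        rng = np.random.default_rng(52)
        cells = rng.integers(0, 40, size=(60, 10, 4))
        cells[:, :, 3] //= 10
        m = _master(cells.tolist())
        base = CallingParams(min_avg_depth=0, max_avg_depth=10**9, min_called_frac=0.0)
        n_base = len(call_snps(m, base))
        for stricter in (
            CallingParams(alt_strength=0.95, min_avg_depth=0, max_avg_depth=10**9, min_called_frac=0.0),
            CallingParams(indep_min_depth=6, min_avg_depth=0, max_avg_depth=10**9, min_called_frac=0.0),
            CallingParams(min_avg_depth=0, max_avg_depth=10**9, min_called_frac=0.5),
        ):
            assert len(call_snps(m, stricter)) <= n_base
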