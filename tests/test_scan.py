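"""Sex-linked SNP scan: MAF, exact HWE, cosegregation, LD, boundaries."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitis_sdr as v
from vitis_sdr.scan import hwe_exact, ld_r2, sdr_boundaries, site_maf


def hwe_exact_oracle(n_homref: int, n_het: int, n_homalt: int) -> Fraction:
    """Exact-rational enumeration of the conditional HWE distribution.

    Independent of the implementation: counts the genotype configurations
    for every compatible heterozygote count with exact integer arithmetic
    and sums the probabilities of configurations no more likely than the
    observed one.
    """
    n = n_homref + n_het + n_homalt
    n_alt = 2 * n_homalt + n_het
    n_ref = 2 * n_homref + n_het
    n_rare = min(n_ref, n_alt)
    if n_rare == 0:
        return Fraction(1)

    def ways(k: int) -> int:
        hom_rare = (n_rare - k) // 2
        hom_common = n - k - hom_rare
        # multinomial count of genotype assignments times 2^het phase choices
        return (
            comb(n, hom_rare) * comb(n - hom_rare, k) * (2 ** k)
        )

    ks = range(n_rare % 2, n_rare + 1, 2)
    total = sum(ways(k) for k in ks)
    probs = {k: Fraction(ways(k), total) for k in ks}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


class TestSiteMaf:
    def test_half_hom_ref_half_het(self):
        g = [0] * 13 + [1] * 13
        assert site_maf(g) == pytest.approx(13 / 52)

    def test_monomorphic_is_zero(self):
        assert site_maf([0] * 20) == 0.0

    def test_minor_allele_can_be_reference(self):
        g = [1] * 5 + [2] * 5
        assert site_maf(g) == pytest.approx(5 / 20)

    def test_missing_excluded_and_all_missing_raises(self):
        assert site_maf([0, 1, -1, -1]) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            site_maf([-1, -1])

    def test_fully_sex_linked_site_closed_form(self, wild_panel):
        # at a fully sex-linked site maf = n_males / (2 (n_f + n_m))
        n_f = (wild_panel.accessions["phenotype"] == "female").sum()
        n_m = (wild_panel.accessions["phenotype"] == "male").sum()
        sl = wild_panel.sites["sex_linked"].to_numpy()
        j = np.flatnonzero(sl)[0]
        assert site_maf(wild_panel.genotypes[:, j]) == pytest.approx(
            n_m / (2 * (n_f + n_m))
        )


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(13, 13, 0), (25, 0, 25), (5, 10, 5), (1, 1, 1), (10, 1, 0), (0, 13, 0)],
    )
    def test_matches_rational_enumeration_oracle(self, counts):
        expected = float(hwe_exact_oracle(*counts))
        assert hwe_exact(*counts) == pytest.approx(expected, rel=1e-9)

    def test_monomorphic_is_one(self):
        assert hwe_exact(0, 0, 10) == 1.0
        assert hwe_exact(10, 0, 0) == 1.0

    def test_extreme_het_deficit_is_minimum_of_support(self):
        # (25, 0, 25) is the least probable configuration given 50/50 alleles
        p = hwe_exact(25, 0, 25)
        oracle = hwe_exact_oracle(25, 0, 25)
        assert p == pytest.approx(float(oracle), rel=1e-9)
        assert p < 1e-12

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)

    @given(
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
        st.integers(min_value=0, max_value=25),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_is_a_probability_and_symmetric(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact(a, b, c)
        assert 0 < p <= 1
        # swapping which homozygote is 'ref' cannot change the test
        assert p == pytest.approx(hwe_exact(c, b, a), rel=1e-9)


class TestCosegregationScan:
    def test_perfect_site_flagged_with_zero_mismatches(self):
        g = np.array([[0] * 5 + [1] * 5]).T.reshape(10, 1)
        labels = ["female"] * 5 + ["male"] * 5
        stats = v.cosegregation_scan(g, [100], labels)
        assert stats.loc[0, "sex_linked"]
        assert stats.loc[0, "coseg_mismatches"] == 0

    def test_sex_independent_site_not_flagged(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(129, 1))
        labels = ["female"] * 65 + ["male"] * 64
        stats = v.cosegregation_scan(g, [100], labels, max_mismatch_frac=0.02)
        assert not stats.loc[0, "sex_linked"]

    def test_error_free_panel_recovers_truth_exactly(self, wild_panel):
        stats = v.cosegregation_scan(
            wild_panel.genotypes, wild_panel.positions, wild_panel.sex_labels()
        )
        flagged = set(stats.loc[stats["sex_linked"], "pos"])
        # every fixed f/M difference cosegregates in a dioecious panel:
        # the sex-linked sites and the H-diagnostic markers in region B
        coseg = wild_panel.sites["kind"].isin(("sex_linked", "b_diagnostic"))
        assert flagged == set(wild_panel.sites.loc[coseg, "pos"])

    def test_sex_linked_sites_violate_hwe(self, model):
        # a wild-panel-sized cohort: all males het, all females hom-ref
        # gives a strong heterozygote excess at every sex-linked site
        panel = v.simulate_panel(model, {"f/f": 65, "M/f": 64}, seed=17)
        stats = v.cosegregation_scan(
            panel.genotypes, panel.positions, panel.sex_labels()
        )
        sl = stats["sex_linked"]
        assert (stats.loc[sl, "hwe_p"] < 1e-3).all()
        neutral = ~np.isin(stats["pos"], model.positions)
        assert stats.loc[neutral, "hwe_p"].median() > 0.1

    def test_hermaphrodites_are_excluded(self, model):
        panel = v.simulate_panel(model, {"f/f": 5, "M/f": 5, "H1/f": 4}, seed=3)
        stats = v.cosegregation_scan(
            panel.genotypes, panel.positions, panel.sex_labels()
        )
        # H1/f would break cosegregation in C/D were it not excluded
        sl_pos = set(panel.sites.loc[panel.sites["sex_linked"], "pos"])
        flagged = set(stats.loc[stats["sex_linked"], "pos"])
        assert sl_pos <= flagged

    def test_too_few_accessions_raise(self):
        with pytest.raises(ValueError):
            v.cosegregation_scan(np.zeros((3, 2)), [1, 2], ["female", "female", "male"])


class TestLd:
    def test_perfect_cosegregation_gives_one(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert ld_r2(a, a.copy()) == pytest.approx(1.0)

    def test_self_ld_is_one(self, wild_panel):
        j = np.flatnonzero(wild_panel.sites["sex_linked"].to_numpy())[0]
        col = wild_panel.genotypes[:, j]
        assert ld_r2(col, col) == pytest.approx(1.0)

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 4000)
        b = rng.integers(0, 3, 4000)
        assert ld_r2(a, b) < 0.01

    def test_monomorphic_reports_missing(self):
        assert np.isnan(ld_r2([0, 0, 0], [0, 1, 2]))

    @given(st.booleans(), st.booleans())
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_invariant_to_allele_recoding(self, swap_a, swap_b):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 0, 2)
        ra = 2 - a if swap_a else a
        rb = 2 - b if swap_b else b
        assert ld_r2(ra, rb) == pytest.approx(ld_r2(a, b), rel=1e-9)

    def test_ld_matrix_long_format(self, wild_panel):
        sl = np.flatnonzero(wild_panel.sites["sex_linked"].to_numpy())[:5]
        df = v.ld_matrix(wild_panel.genotypes[:, sl], wild_panel.positions[sl])
        assert len(df) == 15
        assert np.allclose(df["r2"], 1.0)


class TestSdrBoundaries:
    def test_single_cluster_spans_first_to_last(self):
        pos = [100, 600, 1_000, 1_900]
        assert sdr_boundaries(pos, max_gap_bp=1_000) == (100, 1_900)

    def test_larger_cluster_wins(self):
        pos = [0, 100, 200, 50_000, 50_100, 50_200, 50_300]
        assert sdr_boundaries(pos, max_gap_bp=1_000) == (50_000, 50_300)

    def test_empty_input_returns_none(self):
        assert sdr_boundaries([]) is None

    def test_recovers_simulated_sdr_within_site_spacing(self, model, wild_panel):
        stats = v.cosegregation_scan(
            wild_panel.genotypes, wild_panel.positions, wild_panel.sex_labels()
        )
        interval = sdr_boundaries(stats.loc[stats["sex_linked"], "pos"])
        assert interval is not None
        lo, hi = interval
        # boundaries can only be off by the distance from the SDR edge to
        # its nearest site (~100 bp mean spacing in regions A and D)
        assert model.sdr_start <= lo < model.sdr_start + 1_000
        assert model.sdr_end - 1_500 < hi <= model.sdr_end
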