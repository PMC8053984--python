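"""Behaviour of the synthetic-data generators."""

import numpy as np
import pytest

import vitis_sdr as v
from vitis_sdr.simulate import DEFAULT_EFFECT_SPEC


class TestSimulatePanel:
    def test_error_free_genotypes_equal_template_composition(self, small_model):
        panel = v.simulate_panel(
            small_model, {c: 1 for c in v.CLASSES}, seed=3, n_neutral=0
        )
        for i, row in panel.accessions.iterrows():
            expected = small_model.compose_genotype(row["hap_a"], row["hap_b"])
            assert np.array_equal(panel.genotypes[i], expected)

    def test_ff_accession_is_all_zero_and_mf_all_het(self, small_model):
        panel = v.simulate_panel(small_model, {"f/f": 1, "M/f": 1}, seed=0, n_neutral=0)
        by_label = dict(zip(panel.accessions["class_label"], panel.genotypes))
        assert not by_label["f/f"].any()
        assert (by_label["M/f"] == 1).all()

    def test_reruns_are_byte_identical(self, small_model):
        kw = dict(error_rate=0.02, missing_rate=0.05, seed=42)
        a = v.simulate_panel(small_model, {"f/f": 5, "M/f": 5}, **kw)
        b = v.simulate_panel(small_model, {"f/f": 5, "M/f": 5}, **kw)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.truth_genotypes, b.truth_genotypes)
        assert a.genotypes.tobytes() == b.genotypes.tobytes()

    def test_error_rate_within_three_sigma(self, model):
        rate = 0.02
        panel = v.simulate_panel(model, {"f/f": 10, "M/f": 10}, error_rate=rate, seed=5)
        n_calls = panel.truth_genotypes.size
        assert n_calls >= 10_000
        observed = (panel.genotypes[panel.genotypes >= 0]
                    != panel.truth_genotypes[panel.genotypes >= 0]).mean()
        sigma = np.sqrt(rate * (1 - rate) / n_calls)
        assert abs(observed - rate) < 3 * sigma

    def test_missing_fraction_within_binomial_ci(self, model):
        rate = 0.05
        panel = v.simulate_panel(model, {"f/f": 10, "M/f": 10}, missing_rate=rate, seed=6)
        n = panel.genotypes.size
        observed = (panel.genotypes == -1).mean()
        sigma = np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < 3.5 * sigma

    def test_neutral_sites_live_in_flanks(self, wild_panel):
        neutral = wild_panel.sites["kind"] == "neutral"
        assert neutral.sum() == 150
        pos = wild_panel.sites.loc[neutral, "pos"]
        assert ((pos < 50_000) | (pos >= 195_500)).all()

    def test_empty_class_map_raises(self, small_model):
        with pytest.raises(ValueError):
            v.simulate_panel(small_model, {})
        with pytest.raises(ValueError):
            v.simulate_panel(small_model, {"X/Y": 1})


class TestAlleleDepths:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_panel(small_model):
        return v.simulate_panel(
            small_model, {"f/f": 1, "M/f": 1, "H1/H1": 1}, seed=1, n_neutral=0
        )

    def test_hom_ref_no_error_gives_pure_ref(self, tiny_panel):
        table = v.simulate_allele_depths(tiny_panel, mean_depth=10, base_error=1e-9, seed=2)
        ff = tiny_panel.accessions["class_label"] == "f/f"
        row = np.flatnonzero(ff.to_numpy())[0]
        assert table.alt[row].sum() == 0
        assert table.ref[row].sum() > 0

    def test_het_alt_fraction_near_half(self, tiny_panel):
        table = v.simulate_allele_depths(tiny_panel, mean_depth=50, base_error=0.01, seed=3)
        row = np.flatnonzero((tiny_panel.accessions["class_label"] == "M/f").to_numpy())[0]
        frac = table.alt[row].sum() / table.depth[row].sum()
        # binomial mean 0.5 over ~65 sites x 50 reads
        assert abs(frac - 0.5) < 0.03

    def test_hom_alt_mean_tracks_one_minus_error(self, tiny_panel):
        table = v.simulate_allele_depths(tiny_panel, mean_depth=100, base_error=0.01, seed=4)
        row = np.flatnonzero((tiny_panel.accessions["class_label"] == "H1/H1").to_numpy())[0]
        c_sites = tiny_panel.sites["region"].to_numpy() == "C"  # dosage 2 for H1/H1
        frac = table.alt[row, c_sites].sum() / table.depth[row, c_sites].sum()
        assert abs(frac - 0.99) < 0.01

    def test_missing_genotypes_get_zero_depth(self, small_model):
        panel = v.simulate_panel(small_model, {"f/f": 3}, missing_rate=0.3, seed=9, n_neutral=0)
        table = v.simulate_allele_depths(panel, mean_depth=20, seed=10)
        assert (table.depth[panel.genotypes == -1] == 0).all()

    def test_rna_zeroes_intergenic_sites(self, small_model):
        panel = v.simulate_panel(small_model, {"M/f": 2}, seed=11, n_neutral=0)
        table = v.simulate_allele_depths(
            panel, mean_depth=30, seed=12, source="RNA", model=small_model
        )
        intergenic = small_model.gene_of(panel.positions) == ""
        assert (table.depth[:, intergenic] == 0).all()
        assert table.depth[:, ~intergenic].sum() > 0


class TestAseCounts:
    @pytest.fixture(scope="class")
    @staticmethod
    def ase(small_model):
        panel = v.simulate_panel(
            small_model, {"f/f": 3, "M/f": 3, "H1/f": 3}, seed=21, n_neutral=0
        )
        table = v.simulate_ase_counts(small_model, panel, mean_depth=60, seed=22)
        return panel, table

    def test_only_genic_sites_reported(self, ase, small_model):
        _, table = ase
        assert (small_model.gene_of(table.positions) != "").all()
        assert (table.genes != "").all()

    def test_ff_samples_have_no_alt_reads(self, ase):
        panel, table = ase
        ff = (panel.accessions["class_label"] == "f/f").to_numpy()
        # no M allele present anywhere: alt reads only from base error
        assert table.alt[ff].sum() <= np.ceil(0.01 * table.ref[ff].sum())

    def test_yabby3_m_allele_silenced_in_hermaphrodites(self, ase, small_model):
        panel, table = ase
        # H1/f carries no M allele in region A at all, and the default
        # effect spec silences the M copy of VviYABBY3 outside
        # female-sterile samples; either way alt counts stay at noise level
        herm = (panel.accessions["class_label"] == "H1/f").to_numpy()
        yabby = table.genes == "VviYABBY3"
        assert yabby.any()
        ref = table.ref[np.ix_(herm, yabby)].sum()
        alt = table.alt[np.ix_(herm, yabby)].sum()
        assert ref > 0
        assert alt / (ref + alt) < 0.02  # sequencing error only

    def test_male_yabby3_expression_is_balanced(self, ase):
        panel, table = ase
        male = (panel.accessions["class_label"] == "M/f").to_numpy()
        yabby = table.genes == "VviYABBY3"
        alt = table.alt[np.ix_(male, yabby)].sum()
        depth = alt + table.ref[np.ix_(male, yabby)].sum()
        assert abs(alt / depth - 0.5) < 0.05

    def test_factors_follow_phenotype(self, ase):
        panel, table = ase
        pheno = panel.accessions["phenotype"].to_numpy()
        assert (table.factors["female_sterile"].to_numpy() == (pheno == "male")).all()
        assert (table.factors["male_sterile"].to_numpy() == (pheno == "female")).all()


class TestBulkDepths:
    @pytest.fixture(scope="class")
    @staticmethod
    def tracks(model):
        return v.simulate_bulk_depths(model, unit_coverage=40, seed=31)

    @staticmethod
    def _sdr_mask(track):
        return ~track.flank_mask & (track.ends - track.starts == track.window)

    def test_female_bulk_vanishes_on_m_assembly(self, tracks):
        t = tracks[("female-bulk", "M-hap")]
        assert t.raw[self._sdr_mask(t)].mean() < 0.5

    def test_male_bulk_is_singlefold_on_both(self, tracks):
        for assembly in ("f-hap", "M-hap"):
            t = tracks[("male-bulk", assembly)]
            mean = t.raw[self._sdr_mask(t)].mean()
            assert abs(mean - 40) < 2.5, assembly

    def test_flanks_are_twofold_in_all_tracks(self, tracks):
        for t in tracks.values():
            assert abs(t.raw[t.flank_mask].mean() - 80) < 4

    def test_female_bulk_twofold_on_f_assembly(self, tracks):
        t = tracks[("female-bulk", "f-hap")]
        assert abs(t.raw[self._sdr_mask(t)].mean() - 80) < 4

    def test_window_grid_is_constant_width(self, tracks):
        for t in tracks.values():
            widths = t.ends - t.starts
            assert (widths[:-1] == t.window).all()

    def test_pool_size_validation(self, model):
        with pytest.raises(ValueError):
            v.simulate_bulk_depths(model, n_female=0)
        with pytest.raises(ValueError):
            v.simulate_bulk_depths(model, window=0)


class TestInp1Reads:
    def test_read_length_modes_per_class(self, small_model):
        panel = v.simulate_panel(
            small_model, {"f/f": 1, "M/f": 1, "H1/H2": 1}, seed=41, n_neutral=0
        )
        reads = v.simulate_inp1_read_lengths(panel, depth=200, base_error=0.0, seed=42)
        intact = len(__import__("vitis_sdr").model.INP1_INTACT_SEQ)
        by_label = dict(zip(panel.accessions["class_label"], reads))
        assert set(by_label["f/f"]) == {intact - 8}
        assert set(by_label["M/f"]) == {intact - 8, intact}
        assert set(by_label["H1/H2"]) == {intact}
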