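"""Field projection: matching, abundance accounting, dissimilarity and the
severity regressions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyrotraits.field import (
    TraitAbundanceRecord,
    absolute_abundance,
    bray_curtis_to_unburned,
    copy_number_normalize,
    match_taxa,
    severity_regression,
    trait_total_abundance,
    weighted_mean_copy_number,
)
from pyrotraits.io import CountTable, SampleRecord, TaxonRecord, ValidationError
from pyrotraits.traits import TraitCatalogue


def taxon(tid, seq, cn=1.0):
    return TaxonRecord(tid, seq, cn)


class TestMatchTaxa:
    def test_identical_sequences_match(self):
        seq = "ACGT" * 60
        assert match_taxa([taxon("lab1", seq)], [taxon("f1", seq)]) == {"lab1": "f1"}

    def test_single_mismatch_does_not_match(self):
        seq = "ACGT" * 60
        other = "T" + seq[1:]
        assert match_taxa([taxon("lab1", seq)], [taxon("f1", other)]) == {}

    def test_duplicate_sequences_rejected(self):
        seq = "ACGT" * 60
        with pytest.raises(ValidationError, match="duplicate"):
            match_taxa([taxon("a", seq), taxon("b", seq)], [taxon("f", seq)])

    def test_generator_overlap_fraction_exact(self):
        from pyrotraits.simulate import SimConfig, generate_field_dataset, generate_lab_dataset

        cfg = SimConfig(seed=5, n_taxa=100, n_sites=3, field_lab_overlap=0.8)
        lab = generate_lab_dataset(cfg)
        fld = generate_field_dataset(cfg, lab.taxa, lab.truth)
        match = match_taxa(lab.taxa, fld.taxa)
        assert len(match) / len(lab.taxa) == pytest.approx(0.8)


class TestAbundanceAccounting:
    def _field(self):
        counts = np.array([[10, 50], [30, 30], [60, 20]])
        table = CountTable(["f1", "f2", "f3"], ["s1", "s2"], counts)
        taxa = [taxon("f1", "AAAA", 1.0), taxon("f2", "CCCC", 3.0), taxon("f3", "GGGG", 1.0)]
        samples = [
            SampleRecord("s1", "x1", "dry_burn", "organic", "field", vegetation="pine",
                         years_post_fire=1, burn_severity_index=3.0,
                         qpcr_total_copies_per_g=1e8),
            SampleRecord("s2", "x2", "unburned", "organic", "field", vegetation="pine",
                         years_post_fire=1, burn_severity_index=0.0),
        ]
        return table, taxa, samples

    def test_multi_trait_taxon_counts_once_in_any_trait(self):
        table, taxa, samples = self._field()
        cat = TraitCatalogue(entries={"lab1": {"survivor", "fast_grower"}})
        records = trait_total_abundance(table, cat, {"lab1": "f1"}, taxa, samples)
        by = {(r.sample_id, r.trait): r for r in records}
        assert by[("s1", "survivor")].total_relative_abundance == pytest.approx(0.1)
        assert by[("s1", "fast_grower")].total_relative_abundance == pytest.approx(0.1)
        assert by[("s1", "any_trait")].total_relative_abundance == pytest.approx(0.1)

    def test_absolute_abundance_is_product(self):
        table, taxa, samples = self._field()
        cat = TraitCatalogue(entries={"lab1": {"survivor"}})
        records = trait_total_abundance(table, cat, {"lab1": "f1"}, taxa, samples)
        by = {(r.sample_id, r.trait): r for r in records}
        assert by[("s1", "survivor")].absolute_abundance == pytest.approx(0.1 * 1e8)
        assert by[("s2", "survivor")].absolute_abundance is None  # no qPCR total

    def test_zero_relabund_gives_zero_absolute(self):
        assert absolute_abundance(0.0, 1e8) == 0.0
        assert absolute_abundance(0.25, 1e8) == pytest.approx(2.5e7)


class TestCopyNumberNormalize:
    def test_hand_computed_adjustment(self):
        # counts [10, 30] with copies [1, 3] -> 10 vs 10 -> [0.5, 0.5]
        table = CountTable(["t1", "t2"], ["s1"], np.array([[10], [30]]))
        taxa = [taxon("t1", "AAAA", 1.0), taxon("t2", "CCCC", 3.0)]
        assert np.allclose(copy_number_normalize(table, taxa)[:, 0], [0.5, 0.5])

    def test_equal_copies_is_identity(self, rng):
        counts = rng.integers(1, 100, size=(5, 3))
        table = CountTable([f"t{i}" for i in range(5)], ["a", "b", "c"], counts)
        taxa = [taxon(f"t{i}", "ACGT", 3.0) for i in range(5)]
        from pyrotraits.io import relative_abundance

        assert np.allclose(copy_number_normalize(table, taxa), relative_abundance(table))

    def test_single_taxon_is_one(self):
        table = CountTable(["t1"], ["s1"], np.array([[7]]))
        assert copy_number_normalize(table, [taxon("t1", "AAAA", 4.2)])[0, 0] == 1.0


class TestWeightedMeanCopyNumber:
    def test_weighted_mean(self):
        taxa = [taxon("a", "AAAA", 1.0), taxon("b", "CCCC", 3.0)]
        assert weighted_mean_copy_number([0.5, 0.5], taxa) == pytest.approx(2.0)

    def test_constant_copies(self):
        taxa = [taxon("a", "AAAA", 3.0), taxon("b", "CCCC", 3.0)]
        assert weighted_mean_copy_number([0.2, 0.8], taxa) == pytest.approx(3.0)

    def test_single_taxon(self):
        assert weighted_mean_copy_number([1.0], [taxon("a", "AAAA", 4.2)]) == pytest.approx(4.2)


class TestBrayCurtis:
    def _samples(self, n_burned):
        samples = [
            SampleRecord("u0", "x0", "unburned", "organic", "field", vegetation="pine",
                         years_post_fire=1, burn_severity_index=0.0)
        ]
        for i in range(n_burned):
            samples.append(
                SampleRecord(f"b{i}", f"x{i+1}", "dry_burn", "organic", "field",
                             vegetation="pine", years_post_fire=1,
                             burn_severity_index=2.0)
            )
        return samples

    def test_identical_profiles_give_zero(self):
        counts = np.array([[10, 10], [30, 30]])
        table = CountTable(["t1", "t2"], ["u0", "b0"], counts)
        bc = bray_curtis_to_unburned(table, self._samples(1))
        assert bc["b0"] == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        counts = np.array([[10, 0], [0, 30]])
        table = CountTable(["t1", "t2"], ["u0", "b0"], counts)
        assert bray_curtis_to_unburned(table, self._samples(1))["b0"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # relabund (0.5, 0.5, 0) vs (0, 0.5, 0.5) -> BC = 0.5
        counts = np.array([[2, 0], [2, 2], [0, 2]])
        table = CountTable(["t1", "t2", "t3"], ["u0", "b0"], counts)
        assert bray_curtis_to_unburned(table, self._samples(1))["b0"] == pytest.approx(0.5)

    def test_missing_stratum_is_error(self):
        counts = np.array([[10, 20], [5, 5]])
        table = CountTable(["t1", "t2"], ["b0", "b1"], counts)
        samples = self._samples(2)[1:]  # drop the unburned mate
        with pytest.raises(ValidationError, match="strata"):
            bray_curtis_to_unburned(table, samples)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_random_compositions(self, seed):
        from scipy.spatial.distance import braycurtis

        r = np.random.default_rng(seed)
        x = r.dirichlet(np.ones(8))
        y = r.dirichlet(np.ones(8))
        d = braycurtis(x, y)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert braycurtis(x, y) == pytest.approx(braycurtis(y, x))
        assert braycurtis(x, x) == pytest.approx(0.0)


def severity_records(trait="fast_grower", intercepts=(0.0, 0.0), slopes=(0.5, 0.1),
                     noise=0.0, seed=0, n_per_year=12):
    r = np.random.default_rng(seed)
    records = []
    for year, b0, b1 in zip((1, 5), intercepts, slopes):
        for i in range(n_per_year):
            sev = 5.0 * (i + 1) / n_per_year
            y = b0 + b1 * sev + (r.normal(0, noise) if noise else 0.0)
            records.append(
                TraitAbundanceRecord(f"s{year}_{i}", trait, y, y, None, year, sev)
            )
    return records


class TestSeverityRegression:
    def test_exact_recovery_of_printed_lines(self):
        """Exactly collinear per-year data: y = -0.34 + 0.53x (year 1) and
        y = -0.04 + 0.10x (year 5); coefficients recovered to 1e-8 and the
        interaction retained."""
        records = severity_records(intercepts=(-0.34, -0.04), slopes=(0.53, 0.10))
        fit = severity_regression(records, "fast_grower")
        assert not fit.interaction_dropped
        assert fit.intercept_by_year[1] == pytest.approx(-0.34, abs=1e-8)
        assert fit.slope_by_year[1] == pytest.approx(0.53, abs=1e-8)
        assert fit.intercept_by_year[5] == pytest.approx(-0.04, abs=1e-8)
        assert fit.slope_by_year[5] == pytest.approx(0.10, abs=1e-8)

    def test_constant_response_drops_interaction(self):
        records = severity_records(intercepts=(0.2, 0.2), slopes=(0.0, 0.0), noise=1e-9, seed=3)
        fit = severity_regression(records, "fast_grower")
        assert fit.interaction_dropped
        assert fit.slope_by_year[1] == pytest.approx(0.0, abs=1e-6)

    def test_equal_slopes_drop_interaction_in_most_seeds(self):
        """Interaction-drop calibration: equal year slopes with noise."""
        dropped = 0
        n_seeds = 100
        for seed in range(n_seeds):
            records = severity_records(
                intercepts=(0.1, 0.1), slopes=(0.05, 0.05), noise=0.02, seed=seed
            )
            dropped += severity_regression(records, "fast_grower").interaction_dropped
        assert dropped >= round(0.9 * n_seeds)

    def test_year1_only_slope_flags_interaction(self):
        """Positive year-1 slope, flat year 5: interaction significant in
        >= 80% of seeds at generator-like effect sizes."""
        flagged = 0
        n_seeds = 25
        for seed in range(n_seeds):
            records = severity_records(
                intercepts=(0.02, 0.02), slopes=(0.04, 0.0), noise=0.02, seed=100 + seed
            )
            flagged += not severity_regression(records, "fast_grower").interaction_dropped
        assert flagged >= round(0.8 * n_seeds)

    def test_single_year_is_error(self):
        records = [r for r in severity_records() if r.years_post_fire == 1]
        with pytest.raises(ValidationError, match="year"):
            severity_regression(records, "fast_grower")

    def test_rank_deficiency_is_error(self):
        records = severity_records()
        for r in records:
            r.burn_severity_index = 2.0  # severity constant: collinear
        with pytest.raises(ValidationError, match="rank deficient|collinear"):
            severity_regression(records, "fast_grower")
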