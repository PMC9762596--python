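"""Count-table filtering, rarefaction, taxonomy, agglomeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladal.tables import (AsvTable, SampleMetadata, TaxonomyTable,
                           agglomerate, assign_placeholder_genus,
                           prevalence_filter, rarefy, relative_abundance)
from cladal.tree import ValidationError


def table_from(arr, samples=None, features=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    features = features or [f"f{j}" for j in range(arr.shape[1])]
    return AsvTable(pd.DataFrame(arr, index=samples, columns=features))


class TestAsvTable:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValidationError):
            table_from([[-1, 2]])
        with pytest.raises(ValidationError):
            table_from(np.array([[0.5, 2.0]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError):
            AsvTable(pd.DataFrame([[1, 2]], index=["s"], columns=["a", "a"]))

    def test_tsv_round_trip(self, tmp_path, small_table):
        p = tmp_path / "counts.tsv"
        small_table.to_tsv(p)
        back = AsvTable.read_tsv(p)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)

    def test_tsv_features_in_rows_dialect(self, tmp_path, small_table):
        p = tmp_path / "counts_biom.tsv"
        small_table.to_tsv(p, features_in_rows=True)
        back = AsvTable.read_tsv(p, features_in_rows=True)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)


class TestPrevalenceFilter:
    def test_feature_at_exact_threshold_is_retained(self):
        arr = np.zeros((20, 2), dtype=int)
        arr[:5, 0] = 3   # nonzero in exactly 5 of 20 samples
        arr[:4, 1] = 3   # nonzero in 4 samples: below threshold
        arr[:, 1] += 0
        t = prevalence_filter(table_from(arr), min_samples=5)
        assert t.feature_ids == ["f0"]
        assert t.shape[0] == 20  # sample set unchanged

    def test_threshold_one_drops_only_all_zero_features(self):
        arr = np.array([[0, 1, 0], [0, 2, 0]])
        t = prevalence_filter(table_from(arr), min_samples=1)
        assert t.feature_ids == ["f1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 3, size=(12, 8)))
        once = prevalence_filter(t, 4)
        twice = prevalence_filter(once, 4)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_threshold_above_sample_count_rejected(self, small_table):
        with pytest.raises(ValidationError):
            prevalence_filter(small_table, min_samples=99)


class TestRarefy:
    def test_sample_at_depth_returned_unchanged(self):
        t = table_from([[3, 7], [10, 10]])
        r = rarefy(t, 10, seed=0)
        assert list(r.counts.loc["s0"]) == [3, 7]

    def test_all_samples_sum_to_depth(self):
        rng = np.random.default_rng(1)
        t = table_from(rng.integers(0, 50, size=(8, 15)))
        depth = int(t.sample_totals().min())
        r = rarefy(t, depth, seed=3)
        assert (r.sample_totals() == depth).all()

    def test_zero_count_cannot_gain_reads(self):
        t = table_from([[0, 100, 50]])
        r = rarefy(t, 30, seed=0)
        assert r.counts.iloc[0, 0] == 0

    def test_shallow_samples_dropped_with_warning(self):
        t = table_from([[5, 5], [100, 100]])
        with pytest.warns(UserWarning, match="dropping"):
            r = rarefy(t, 50, seed=0)
        assert r.sample_ids == ["s1"]

    def test_deterministic_for_fixed_seed(self):
        t = table_from([[60, 40, 20]])
        r1 = rarefy(t, 50, seed=11)
        r2 = rarefy(t, 50, seed=11)
        pd.testing.assert_frame_equal(r1.counts, r2.counts)

    def test_mean_matches_hypergeometric_expectation(self):
        # sample (60, 40) rarefied to 50: first feature ~ Hypergeom(100,60,50)
        t = table_from([[60, 40]])
        draws = np.array([rarefy(t, 50, seed=s).counts.iloc[0, 0]
                          for s in range(1000)])
        expected = stats.hypergeom(100, 60, 50).mean()   # = 30
        se = stats.hypergeom(100, 60, 50).std() / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_nonpositive_depth_rejected(self, small_table):
        with pytest.raises(ValidationError):
            rarefy(small_table, 0, seed=0)


class TestTaxonomy:
    def test_placeholder_genus_form(self, small_taxonomy):
        out = assign_placeholder_genus(small_taxonomy)
        assert out.assignments.loc["b", "genus"] == "F1_Genus_b"
        assert out.assignments.loc["d", "genus"] == "F3_Genus_d"

    def test_known_genus_untouched(self, small_taxonomy):
        out = assign_placeholder_genus(small_taxonomy)
        assert out.assignments.loc["a", "genus"] == "G1"

    def test_same_family_unknowns_get_distinct_genera(self):
        df = pd.DataFrame({
            "phylum": ["P", "P"], "class": ["C", "C"], "order": ["O", "O"],
            "family": ["Lachnospiraceae", "Lachnospiraceae"],
            "genus": ["unknown", "unknown"],
        }, index=["ASV17", "ASV18"])
        out = assign_placeholder_genus(TaxonomyTable(df))
        genera = out.assignments["genus"]
        assert genera["ASV17"] == "Lachnospiraceae_Genus_ASV17"
        assert len(set(genera)) == 2
        assert "unknown" not in set(genera)


class TestAgglomerate:
    def test_genus_counts_are_member_sums(self, small_table, small_taxonomy):
        tax = assign_placeholder_genus(small_taxonomy)
        g = agglomerate(small_table, tax, "genus")
        # a (G1) alone; b its own placeholder genus
        assert g.counts.loc["s2", "G1"] == 0
        assert g.counts.loc["s1", "G1"] == 2
        assert g.counts.loc["s2", "F1_Genus_b"] == 5

    def test_single_phylum_collapses_to_sample_totals(self):
        t = table_from([[1, 2], [3, 4]])
        df = pd.DataFrame({r: ["X", "X"] for r in
                           ("phylum", "class", "order", "family", "genus")},
                          index=["f0", "f1"])
        g = agglomerate(t, TaxonomyTable(df), "phylum")
        assert list(g.counts["X"]) == [3, 7]

    @pytest.mark.parametrize("rank", ["phylum", "class", "order", "family"])
    def test_per_sample_totals_conserved(self, rank):
        rng = np.random.default_rng(7)
        t = table_from(rng.integers(0, 9, size=(5, 8)))
        df = pd.DataFrame({
            "phylum": rng.choice(["P1", "P2"], 8),
            "class": rng.choice(["C1", "C2", "C3"], 8),
            "order": rng.choice(["O1", "O2"], 8),
            "family": rng.choice(["F1", "F2", "F3"], 8),
            "genus": [f"G{i}" for i in range(8)],
        }, index=t.feature_ids)
        g = agglomerate(t, TaxonomyTable(df), rank)
        assert (g.sample_totals() == t.sample_totals()).all()

    def test_unknown_rank_rejected(self, small_table, small_taxonomy):
        with pytest.raises(ValidationError, match="rank"):
            agglomerate(small_table, small_taxonomy, "kingdom")


class TestRelativeAbundance:
    def test_simple_proportions(self):
        rel = relative_abundance(table_from([[1, 1], [10, 0]]))
        assert list(rel.iloc[0]) == [0.5, 0.5]
        assert list(rel.iloc[1]) == [1.0, 0.0]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        rel = relative_abundance(table_from(rng.integers(1, 50, size=(6, 9))))
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named_in_error(self):
        with pytest.raises(ValidationError, match="s1"):
            relative_abundance(table_from([[1, 2], [0, 0]],
                                          samples=["s0", "s1"]))


class TestSampleMetadata:
    def test_rejects_varying_diet_within_host(self):
        df = pd.DataFrame({
            "host_id": ["h1", "h1"], "age": ["young", "young"],
            "diet": ["ZA", "ZD"], "study": ["ZAM2", "ZAM2"],
            "timepoint": ["wk0", "wk6"], "il6": [np.nan, 50.0],
        }, index=["h1_wk0", "h1_wk6"])
        with pytest.raises(ValidationError, match="constant within host"):
            SampleMetadata(df)

    def test_rejects_duplicate_host_timepoint(self):
        df = pd.DataFrame({
            "host_id": ["h1", "h1"], "age": ["young", "young"],
            "diet": ["ZA", "ZA"], "study": ["ZAM1", "ZAM1"],
            "timepoint": ["wk6", "wk6"], "il6": [50.0, 60.0],
        }, index=["a", "b"])
        with pytest.raises(ValidationError, match="unique"):
            SampleMetadata(df)

    def test_rejects_invalid_levels(self):
        df = pd.DataFrame({
            "host_id": ["h1"], "age": ["middle"], "diet": ["ZA"],
            "study": ["ZAM1"], "timepoint": ["wk0"], "il6": [np.nan],
        }, index=["x"])
        with pytest.raises(ValidationError, match="age"):
            SampleMetadata(df)
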