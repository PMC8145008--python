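import numpy as np
import pandas as pd
import pytest

from viromedeck.virome_standardize import (
    StandardizeConfig,
    apply_abundance_threshold,
    classified_fraction,
    log10_matrix,
    normalize_per_kb,
    plant_equivalents,
    standardize,
    subtract_control_contamination,
)

from conftest import make_count_table


def taxa_meta(lengths: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": list(lengths),
            "host_class": ["arthropod"] * len(lengths),
            "contig_length_kb": list(lengths.values()),
        },
        index=pd.Index(list(lengths), name="taxon_id"),
    )


class TestAbundanceThreshold:
    def test_exactly_one_in_ten_thousand_is_removed(self):
        table = make_count_table(
            {"famA": {"s1": 1}, "famB": {"s1": 2}},
            roles={"s1": "specimen"}, totals={"s1": 10_000},
        )
        out, log = apply_abundance_threshold(table)
        assert out.counts.loc["famA", "s1"] == 0  # 1/10,000 is not > 1/10,000
        assert out.counts.loc["famB", "s1"] == 2  # 2/10,000 exceeds it
        assert list(log["taxon_id"]) == ["famA"]

    def test_matches_per_cell_brute_force(self, rng):
        taxa = [f"t{i}" for i in range(15)]
        counts = {t: {"s1": int(rng.integers(0, 6)), "s2": int(rng.integers(0, 6))} for t in taxa}
        table = make_count_table(
            counts, roles={"s1": "specimen", "s2": "specimen"},
            totals={"s1": 20_000, "s2": 30_000},
        )
        out, _ = apply_abundance_threshold(table)
        for t in taxa:
            for s in ("s1", "s2"):
                c = counts[t][s]
                tot = table.samples.loc[s, "total_cleaned_reads"]
                expected = c if c / tot > 1e-4 else 0
                assert out.counts.loc[t, s] == expected

    def test_never_increases_any_cell(self, small_community):
        table, _ = small_community
        out, _ = apply_abundance_threshold(table)
        assert (out.counts.values <= table.counts.values).all()


class TestControlSubtraction:
    def test_taxon_absent_from_controls_untouched(self):
        table = make_count_table(
            {"famA": {"s1": 100, "nc1": 0}},
            roles={"s1": "specimen", "nc1": "negative_control"},
            totals={"s1": 1000, "nc1": 1000},
        )
        out, log = subtract_control_contamination(table)
        assert out.counts.loc["famA", "s1"] == 100
        assert log.empty

    def test_equal_abundance_is_removed_inclusive(self):
        table = make_count_table(
            {"famA": {"s1": 5, "s2": 6, "nc1": 5}},
            roles={"s1": "specimen", "s2": "specimen", "nc1": "negative_control"},
            totals={"s1": 1000, "s2": 1000, "nc1": 1000},
        )
        out, _ = subtract_control_contamination(table)
        assert out.counts.loc["famA", "s1"] == 0  # equal to control: removed
        assert out.counts.loc["famA", "s2"] == 6  # strictly above: kept

    def test_maximum_across_controls_is_the_comparator(self):
        table = make_count_table(
            {"famA": {"s1": 5, "nc1": 1, "nc2": 8}},
            roles={"s1": "specimen", "nc1": "negative_control", "nc2": "negative_control"},
            totals={"s1": 1000, "nc1": 1000, "nc2": 1000},
        )
        out, _ = subtract_control_contamination(table)
        assert out.counts.loc["famA", "s1"] == 0

    def test_raw_basis_ignores_library_depth(self):
        table = make_count_table(
            {"famA": {"s1": 5, "nc1": 6}},
            roles={"s1": "specimen", "nc1": "negative_control"},
            totals={"s1": 100, "nc1": 1_000_000},
        )
        cfg = StandardizeConfig(control_comparison_basis="raw")
        out, _ = subtract_control_contamination(table, cfg)
        assert out.counts.loc["famA", "s1"] == 0
        out_rel, _ = subtract_control_contamination(table)
        assert out_rel.counts.loc["famA", "s1"] == 5  # relative basis keeps it

    def test_no_controls_is_an_error(self):
        table = make_count_table({"famA": {"s1": 1}}, roles={"s1": "specimen"})
        with pytest.raises(ValueError, match="negative_control"):
            subtract_control_contamination(table)

    def test_planted_contamination_fully_removed(self, small_community):
        """With leaks entering controls at full donor intensity, every planted
        contaminant cell is zeroed and no resident above control level is."""
        table, truth = small_community
        out, log = standardize(table)
        rel = table.relative_abundance()
        ctrl_max = rel[table.control_ids].max(axis=1)
        for taxon, sample in truth.contaminant_cells():
            if sample in table.control_ids:
                continue
            assert out.counts.loc[taxon, sample] == 0
        removed = set(zip(log["taxon_id"], log["sample_id"]))
        for taxon, sample in removed:
            flag = truth.flags.loc[taxon, sample]
            if flag == "resident":
                # a removed resident must not have been strictly above control level
                assert rel.loc[taxon, sample] <= ctrl_max[taxon] or (
                    rel.loc[taxon, sample] <= 1e-4  # or fell to the abundance threshold
                )

    def test_standardize_is_idempotent(self, small_community):
        table, _ = small_community
        once, _ = standardize(table)
        twice, log2 = standardize(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert log2.empty


class TestNormalizePerKb:
    def test_reads_per_kb_arithmetic(self):
        table = make_count_table(
            {"famA": {"s1": 1000}, "famB": {"s1": 0}},
            roles={"s1": "specimen"},
            taxa_meta=taxa_meta({"famA": 2.0, "famB": 4.0}),
        )
        out = normalize_per_kb(table)
        assert out.loc["famA", "s1"] == 500.0
        assert out.loc["famB", "s1"] == 0.0

    def test_doubling_lengths_halves_values(self, rng):
        taxa = {f"t{i}": float(rng.uniform(0.5, 20)) for i in range(8)}
        counts = {t: {"s1": int(rng.integers(0, 5000))} for t in taxa}
        t1 = make_count_table(counts, roles={"s1": "specimen"}, taxa_meta=taxa_meta(taxa))
        t2 = make_count_table(
            counts, roles={"s1": "specimen"},
            taxa_meta=taxa_meta({k: 2 * v for k, v in taxa.items()}),
        )
        np.testing.assert_allclose(normalize_per_kb(t1).values, 2 * normalize_per_kb(t2).values)

    def test_missing_length_with_reads_is_an_error(self):
        table = make_count_table(
            {"famA": {"s1": 10}}, roles={"s1": "specimen"},
            taxa_meta=taxa_meta({"famA": 0.0}),
        )
        with pytest.raises(ValueError, match="contig_length_kb"):
            normalize_per_kb(table)


class TestLog10Matrix:
    def test_zero_maps_to_zero_and_999_to_three(self):
        table = make_count_table(
            {"famA": {"s1": 0}, "famB": {"s1": 999}}, roles={"s1": "specimen"}
        )
        out = log10_matrix(table)
        assert out.loc["famA", "s1"] == 0.0
        assert out.loc["famB", "s1"] == 3.0

    def test_monotone_in_count(self, rng):
        counts = np.sort(rng.integers(0, 100_000, 50))
        table = make_count_table(
            {f"t{i}": {"s1": int(c)} for i, c in enumerate(counts)},
            roles={"s1": "specimen"},
        )
        vals = log10_matrix(table)["s1"].to_numpy()
        assert (np.diff(vals) >= 0).all()


class TestClassifiedFraction:
    def test_fraction_and_summary(self):
        frac, stats = classified_fraction(
            pd.Series({"a": 41, "b": 0}), pd.Series({"a": 100, "b": 100})
        )
        assert frac["a"] == 0.41
        assert frac["b"] == 0.0
        assert stats == {"min": 0.0, "mean": 0.205, "max": 0.41}

    def test_classified_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            classified_fraction(pd.Series({"a": 101}), pd.Series({"a": 100}))

    def test_mean_is_arithmetic_mean_of_fractions(self, rng):
        totals = pd.Series(rng.integers(1000, 5000, 10), index=[f"s{i}" for i in range(10)])
        classified = pd.Series(
            [int(rng.integers(0, t + 1)) for t in totals], index=totals.index
        )
        frac, stats = classified_fraction(classified, totals)
        assert stats["mean"] == pytest.approx(frac.mean())


class TestPlantEquivalents:
    def test_survey_lower_bound(self):
        assert plant_equivalents(14, 50) == 700

    def test_identity_and_commutativity(self):
        assert plant_equivalents(1, 1) == 1
        assert plant_equivalents(3, 17) == plant_equivalents(17, 3)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            plant_equivalents(0, 5)
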