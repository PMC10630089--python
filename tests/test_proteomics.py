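"""Filtering, normalization, MNAR imputation and enrichment testing."""

import numpy as np
import pandas as pd
import pytest

from corona_evo.proteomics import (
    IntensityTable,
    filter_proteins,
    impute_mnar,
    normalize_vst,
    test_enrichment as run_enrichment,
    volcano_table,
)


def make_table(values, peptides=None, conditions=("A", "A", "A", "B", "B", "B"),
               scale="log2"):
    values = pd.DataFrame(values)
    n = len(conditions)
    samples = []
    seen: dict[str, int] = {}
    for cond in conditions:
        seen[cond] = seen.get(cond, 0) + 1
        samples.append(f"{cond}_{seen[cond]}")
    values.columns = samples
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": list(conditions),
            "replicate": [int(s.split("_")[1]) for s in samples],
        }
    )
    if peptides is None:
        peptides = pd.Series(5, index=values.index)
    else:
        peptides = pd.Series(peptides, index=values.index)
    return IntensityTable(values=values, design=design, unique_peptides=peptides,
                          scale=scale)


class TestFilterProteins:
    def test_hand_enumerated_survivor_set(self):
        nan = np.nan
        # six proteins crafted to exercise every clause
        values = {
            "keep_full": [25, 25, 25, 25, 25, 25],     # observed everywhere
            "keep_one_cond": [25, 25, 25, nan, nan, nan],  # 3/3 in A only
            "drop_sparse": [25, nan, nan, nan, 25, nan],   # 1/3 in each
            "keep_two_in_b": [nan, nan, 25, 25, 25, nan],  # 2/3 in B
            "drop_no_peptides": [25, 25, 25, 25, 25, 25],  # fails peptide rule
            "drop_all_missing": [nan, nan, nan, nan, nan, nan],
        }
        frame = pd.DataFrame(values).T
        peptides = [2, 2, 2, 2, 0, 2]
        table = make_table(frame, peptides=peptides)
        kept = filter_proteins(table, min_unique_peptides=1, min_reps=2)
        assert list(kept.values.index) == ["keep_full", "keep_one_cond", "keep_two_in_b"]

    def test_observed_in_one_condition_with_peptides_kept(self):
        nan = np.nan
        table = make_table(pd.DataFrame([[25, 25, 25, nan, nan, nan]]), peptides=[2])
        assert len(filter_proteins(table).values) == 1

    def test_one_in_each_condition_removed(self):
        nan = np.nan
        table = make_table(pd.DataFrame([[25, nan, nan, 25, nan, nan]]), peptides=[5])
        assert len(filter_proteins(table).values) == 0

    def test_empty_table_passes_through(self):
        table = make_table(pd.DataFrame(np.empty((0, 6))), peptides=[])
        assert len(filter_proteins(table).values) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(25, 2, size=(20, 6))
        arr[rng.random(arr.shape) < 0.3] = np.nan
        table = make_table(pd.DataFrame(arr), peptides=rng.poisson(3, 20))
        once = filter_proteins(table)
        twice = filter_proteins(once)
        assert once.values.equals(twice.values)

    def test_too_few_samples_in_condition_rejected(self):
        table = make_table(pd.DataFrame([[25.0, 25, 25, 25]]),
                           conditions=("A", "A", "A", "B"), peptides=[5])
        with pytest.raises(ValueError):
            filter_proteins(table, min_reps=2)


class TestNormalizeVst:
    def test_identical_groups_unchanged(self):
        arr = np.array([[24.0, 24, 24, 24, 24, 24], [28.0, 28, 28, 28, 28, 28]])
        table = make_table(pd.DataFrame(arr))
        out = normalize_vst(table)
        np.testing.assert_allclose(out.values.to_numpy(), arr)

    def test_constant_group_shift_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(25, 2, size=(50, 3))
        arr = np.column_stack([base, base + 3.0])  # group B = group A + c
        table = make_table(pd.DataFrame(arr))
        out = normalize_vst(table).values.to_numpy()
        np.testing.assert_allclose(out[:, :3], out[:, 3:], rtol=0, atol=1e-9)

    def test_missing_stays_missing(self):
        arr = np.array([[24.0, np.nan, 25, 26, 27, np.nan]])
        table = make_table(pd.DataFrame(arr))
        out = normalize_vst(table)
        assert np.isnan(out.values.to_numpy()[0, [1, 5]]).all()

    def test_raw_scale_is_log_transformed(self):
        arr = np.array([[2.0**20, 2.0**20, 2.0**20, 2.0**20, 2.0**20, 2.0**20]])
        table = make_table(pd.DataFrame(arr), scale="raw")
        out = normalize_vst(table)
        np.testing.assert_allclose(out.values.to_numpy(), 20.0)

    def test_variance_stabilized_on_heteroscedastic_raw_data(self):
        """On raw-scale data whose noise SD scales with the mean, the
        high/low-intensity spread ratio collapses after the transform."""
        rng = np.random.default_rng(2)
        ratios_before, ratios_after = [], []
        for _ in range(100):
            means = 2.0 ** rng.uniform(18, 30, size=150)
            raw = means[:, None] * rng.lognormal(0, 0.3, size=(150, 6))
            table = make_table(pd.DataFrame(raw), scale="raw")
            row_sd_raw = raw.std(axis=1)
            out = normalize_vst(table).values.to_numpy()
            row_sd_log = out.std(axis=1)
            order = np.argsort(means)
            low, high = order[:50], order[-50:]
            ratios_before.append(row_sd_raw[high].mean() / row_sd_raw[low].mean())
            ratios_after.append(row_sd_log[high].mean() / row_sd_log[low].mean())
        assert np.mean(ratios_before) > 3.0
        assert abs(np.mean(ratios_after) - 1.0) < 0.2

    def test_all_missing_group_rejected(self):
        arr = np.array([[24.0, 25, 26, np.nan, np.nan, np.nan]])
        table = make_table(pd.DataFrame(arr))
        with pytest.raises(ValueError):
            normalize_vst(table)


class TestImputeMnar:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(25, 2, size=(30, 6))
        table = make_table(pd.DataFrame(arr))
        out = impute_mnar(table, seed=1)
        np.testing.assert_array_equal(out.values.to_numpy(), arr)

    def test_degenerate_gaussian_hits_sample_mean(self):
        arr = np.array([[20.0, 24, 28, np.nan, 25, 25],
                        [22.0, 26, 24, 25.0, 25, 25],
                        [24.0, 25, 26, 27.0, 25, 25]])
        table = make_table(pd.DataFrame(arr))
        out = impute_mnar(table, shift_sd=0.0, width_sd=1e-12, seed=2)
        observed_mean = np.nanmean(arr[:, 3])
        assert out.values.to_numpy()[0, 3] == pytest.approx(observed_mean, abs=1e-6)

    def test_draw_mean_matches_left_shifted_gaussian(self):
        """Mean of 10,000 imputed draws sits at mean − 1.8·SD within 3 SE."""
        rng = np.random.default_rng(4)
        n = 20000
        col = rng.normal(25, 2, size=n)
        missing = rng.random(n) < 0.5
        arr = col.copy()
        arr[missing] = np.nan
        frame = pd.DataFrame(
            {"S_1": arr, **{f"S_{i}": col for i in range(2, 7)}}
        )
        frame.columns = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
        table = make_table(frame)
        out = impute_mnar(table, shift_sd=1.8, width_sd=0.3, seed=5)
        observed = col[~missing]
        target = observed.mean() - 1.8 * observed.std(ddof=1)
        draws = out.values.to_numpy()[missing, 0]
        se = 0.3 * observed.std(ddof=1) / np.sqrt(missing.sum())
        assert abs(draws.mean() - target) < 3 * se

    def test_observed_values_untouched_and_seed_reproducible(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(25, 2, size=(40, 6))
        arr[rng.random(arr.shape) < 0.2] = np.nan
        table = make_table(pd.DataFrame(arr))
        out1 = impute_mnar(table, seed=7)
        out2 = impute_mnar(table, seed=7)
        assert out1.values.equals(out2.values)
        mask = ~np.isnan(arr)
        np.testing.assert_array_equal(out1.values.to_numpy()[mask], arr[mask])

    def test_imputed_values_fall_below_sample_median(self):
        """Left-shifted property: imputed draws lie below the observed median
        of their sample essentially always under the defaults."""
        rng = np.random.default_rng(8)
        arr = rng.normal(25, 2, size=(500, 6))
        mask = rng.random(arr.shape) < 0.2
        arr2 = arr.copy()
        arr2[mask] = np.nan
        table = make_table(pd.DataFrame(arr2))
        out = impute_mnar(table, seed=9).values.to_numpy()
        medians = np.nanmedian(arr2, axis=0)
        below = out[mask] < np.broadcast_to(medians, arr.shape)[mask]
        assert below.mean() >= 0.99

    def test_sparse_sample_rejected(self):
        arr = np.array([[25.0, np.nan, 24, 25, 25, 25],
                        [np.nan, np.nan, 24, 25, 25, 25]])
        table = make_table(pd.DataFrame(arr))
        with pytest.raises(ValueError):
            impute_mnar(table, seed=1)


class TestEnrichment:
    def test_identical_values_not_a_hit(self):
        arr = np.array([[25.0, 25, 25, 25, 25, 25]])
        result = run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")
        row = result.table.iloc[0]
        assert row.log2fc == 0 and row.p_value == 1.0 and not row.hit

    def test_threshold_rule(self):
        rng = np.random.default_rng(10)
        base = 25 + rng.normal(0, 0.05, size=3)
        arr = np.array([np.concatenate([base + 2.5, base])])
        result = run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")
        row = result.table.iloc[0]
        assert row.log2fc == pytest.approx(2.5, abs=0.2)
        assert row.neg_log10_p > 2
        assert bool(row.hit)

    def test_hit_flag_consistent_with_thresholds(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(25, 1, size=(200, 6))
        arr[:20, :3] += rng.uniform(0, 5, size=(20, 1))
        result = run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")
        t = result.table
        expected = (t.log2fc > 2) & (t.neg_log10_p > 2)
        assert (t.hit == expected).all()
        np.testing.assert_allclose(t.neg_log10_p, -np.log10(t.p_value))

    def test_pooled_vs_welch_differ_only_in_p(self):
        rng = np.random.default_rng(12)
        arr = rng.normal(25, 1, size=(50, 6))
        table = make_table(pd.DataFrame(arr))
        welch = run_enrichment(table, "A", "B", test="welch")
        pooled = run_enrichment(table, "A", "B", test="pooled")
        np.testing.assert_allclose(welch.table.log2fc, pooled.table.log2fc)
        assert not np.allclose(welch.table.p_value, pooled.table.p_value)

    def test_unknown_condition_rejected(self):
        arr = np.zeros((1, 6)) + 25
        with pytest.raises(KeyError):
            run_enrichment(make_table(pd.DataFrame(arr)), "A", "nope")

    def test_missing_values_rejected(self):
        arr = np.array([[25.0, np.nan, 25, 25, 25, 25]])
        with pytest.raises(ValueError):
            run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")


class TestVolcanoTable:
    def test_single_row(self):
        arr = np.array([[25.0, 25, 25, 25, 25, 25]])
        result = run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")
        assert len(volcano_table(result)) == 1

    def test_hits_rank_first_then_significance(self):
        rng = np.random.default_rng(13)
        arr = rng.normal(25, 0.3, size=(30, 6))
        arr[5, :3] += 6  # clear hit
        result = run_enrichment(make_table(pd.DataFrame(arr)), "A", "B")
        ranked = volcano_table(result)
        assert bool(ranked.iloc[0].hit)
        nonhits = ranked[~ranked.hit]
        assert (nonhits.neg_log10_p.diff().dropna() <= 1e-12).all()

    def test_p_ties_broken_by_fold_change_then_name(self):
        arr = np.array(
            [
                [25.0, 25, 25, 25, 25, 25],
                [27.0, 27, 27, 25, 25, 25],
                [26.0, 26, 26, 25, 25, 25],
            ]
        )
        table = make_table(pd.DataFrame(arr, index=["b_zero", "a_big", "c_small"]))
        ranked = volcano_table(run_enrichment(table, "A", "B"))
        assert list(ranked.protein[:2]) == ["a_big", "c_small"]
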