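import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
import scipy.cluster.hierarchy as sch

from phosphodiff import (
    ConfigurationError,
    NormalizedTable,
    cross_layer_correlation,
    hierarchical_cluster,
    log2_zscore,
    valid_value_filter,
    PHOSPHO,
)
from .conftest import build_design, make_table


def norm_from(values, design, layer="proteome", genes=None):
    frame = pd.DataFrame(values, columns=design.samples)
    frame.index = [f"P{i:03d}" for i in range(len(frame))]
    return NormalizedTable(values=frame, design=design, layer=layer, axis="sample",
                           gene_symbols=pd.Series(genes, index=frame.index)
                           if genes is not None else None)


class TestLog2Zscore:
    def test_hand_example_column(self, design4):
        # one column {1, 2, 4} -> log2 {0, 1, 2} -> z {-1, 0, 1}
        values = np.ones((3, 12))
        values[:, 0] = [1.0, 2.0, 4.0]
        norm = log2_zscore(make_table(values, design4), axis="sample")
        np.testing.assert_allclose(norm.values.iloc[:, 0], [-1.0, 0.0, 1.0])

    def test_missing_stays_missing(self, design4):
        values = np.exp(np.random.default_rng(0).normal(size=(6, 12)))
        values[2, 5] = np.nan
        norm = log2_zscore(make_table(values, design4))
        assert np.isnan(norm.values.iloc[2, 5])
        assert norm.valid_mask.iloc[2, 5] == False  # noqa: E712

    def test_zero_variance_column_becomes_zeros(self, design4):
        values = np.full((4, 12), 3.0)
        norm = log2_zscore(make_table(values, design4))
        np.testing.assert_allclose(norm.values.to_numpy(), 0.0)

    @pytest.mark.parametrize("axis,np_axis", [("sample", 0), ("feature", 1)])
    def test_valid_entries_standardized(self, design4, axis, np_axis):
        rng = np.random.default_rng(1)
        values = np.exp(rng.normal(size=(30, 12)))
        values[rng.random((30, 12)) < 0.2] = np.nan
        norm = log2_zscore(make_table(values, design4), axis=axis)
        means = np.nanmean(norm.values.to_numpy(), axis=np_axis)
        sds = np.nanstd(norm.values.to_numpy(), axis=np_axis, ddof=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)
        assert norm.axis == axis


class TestValidValueFilter:
    def test_two_of_three_rule(self, design4):
        values = np.exp(np.zeros((2, 12)))
        # feature 0: 3 valid in three lines, only 1 valid in CRB -> removed
        values[0, 10:] = np.nan
        kept, removed = valid_value_filter(make_table(values, design4), 2)
        assert list(kept.feature_ids) == ["P001"]
        assert list(removed.feature_ids) == ["P000"]

    def test_threshold_above_replicates_is_error(self, design4):
        with pytest.raises(ConfigurationError, match="exceeds"):
            valid_value_filter(make_table(np.ones((2, 12)), design4), 4)

    def test_antitone_in_threshold(self, design4):
        rng = np.random.default_rng(7)
        values = np.exp(rng.normal(size=(60, 12)))
        values[rng.random((60, 12)) < 0.4] = np.nan
        table = make_table(values, design4)
        sizes = [len(valid_value_filter(table, k).kept) for k in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_reduced_design_uses_reduced_replicate_count(self, design4):
        # after dropping a replicate the rule is >=2 of 2 for that line
        values = np.exp(np.zeros((1, 12)))
        values[0, 11] = np.nan  # CRB_3
        table = make_table(values, design4).drop_sample("CRB_3")
        kept, _ = valid_value_filter(table, 2)
        assert len(kept) == 1
        table2 = make_table(values, design4).drop_sample("CRB_2")
        kept2, _ = valid_value_filter(table2, 2)
        assert len(kept2) == 0  # only CRB_1 valid of the remaining two


class TestHierarchicalCluster:
    def test_identical_columns_merge_first_at_zero(self, design4):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 12))
        values[:, 1] = values[:, 0]
        dend = hierarchical_cluster(norm_from(values, design4))
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_average_linkage_matches_manual_upgma(self):
        # four 1-D points {0, 1, 3, 7}: merges at 1, 2.5, 17/3
        design = build_design({"A": "CS", "B": "CR"}, replicates=2)
        values = np.array([[0.0, 1.0, 3.0, 7.0]])
        dend = hierarchical_cluster(norm_from(values, design))
        np.testing.assert_allclose(sorted(dend.linkage[:, 2]), [1.0, 2.5, 17 / 3])

    def test_heights_invariant_to_feature_and_sample_order(self, design4):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 12))
        base = hierarchical_cluster(norm_from(values, design4))
        shuffled = values[rng.permutation(40), :]
        perm = hierarchical_cluster(norm_from(shuffled, design4))
        np.testing.assert_allclose(np.sort(base.linkage[:, 2]),
                                   np.sort(perm.linkage[:, 2]))

    def test_missing_handling_scales_to_full_euclidean(self, design4):
        # with complete data the distance equals plain Euclidean
        rng = np.random.default_rng(4)
        values = rng.normal(size=(25, 12))
        dend = hierarchical_cluster(norm_from(values, design4))
        reference = sch.linkage(pdist(values.T), method="average")
        np.testing.assert_allclose(dend.linkage[:, 2], reference[:, 2])

    def test_disjoint_supports_error(self, design4):
        values = np.full((4, 12), np.nan)
        values[:2, 0] = 1.0
        values[2:, 1] = 1.0
        values[:, 2:] = 0.5
        with pytest.raises(ConfigurationError, match="share no valid"):
            hierarchical_cluster(norm_from(values, design4))

    def test_replicates_cluster_together_with_strong_line_effects(self, design4):
        rng = np.random.default_rng(5)
        line_effects = {"BEN": 0.0, "CSL": 4.0, "CRA": 8.0, "CRB": 12.0}
        values = np.zeros((50, 12))
        for j, s in enumerate(design4.samples):
            values[:, j] = rng.normal(line_effects[design4.line_of(s)], 0.5, size=50)
        dend = hierarchical_cluster(norm_from(values, design4))
        assert dend.replicate_coherence == 1.0


class TestCrossLayerCorrelation:
    def make_pair(self, design4, site_values, prot_values, parents):
        prot = norm_from(prot_values, design4)
        sites = pd.DataFrame(site_values, columns=design4.samples)
        sites.index = [f"{p}_S{i+1}" for i, p in enumerate(parents)]
        phos = NormalizedTable(values=sites, design=design4, layer=PHOSPHO, axis="sample")
        return prot, phos

    def test_identical_layers_give_unit_correlation(self, design4):
        rng = np.random.default_rng(6)
        prot_values = rng.normal(size=(8, 12))
        parents = [f"P{i:03d}" for i in range(8)]
        prot, phos = self.make_pair(design4, prot_values.copy(), prot_values, parents)
        corr, n_shared = cross_layer_correlation(prot, phos)
        assert n_shared == 8
        np.testing.assert_allclose(corr.to_numpy(), 1.0)

    def test_matches_hand_computed_pearson(self, design4):
        prot_values = np.arange(48, dtype=float).reshape(4, 12)
        site_values = prot_values[::-1].copy()  # reversed pairing
        parents = [f"P{i:03d}" for i in range(4)]
        prot, phos = self.make_pair(design4, site_values, prot_values, parents)
        corr, _ = cross_layer_correlation(prot, phos)
        for line in design4.cell_lines:
            cols = design4.samples_for_line(line)
            x = prot.values[cols].mean(axis=1).to_numpy()
            # site i belongs to parent i but carries protein (3-i)'s values
            y = phos.values[cols].mean(axis=1).to_numpy()
            expected = np.corrcoef(x, y)[0, 1]
            assert corr[line] == pytest.approx(expected)

    def test_too_few_shared_proteins_is_error(self, design4):
        prot_values = np.random.default_rng(0).normal(size=(2, 12))
        prot, phos = self.make_pair(design4, prot_values, prot_values,
                                    ["P000", "P001"])
        with pytest.raises(ConfigurationError, match="fewer than 3"):
            cross_layer_correlation(prot, phos)
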