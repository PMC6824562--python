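import numpy as np
import pandas as pd
import pytest

from phosphodiff import (
    ConfigurationError,
    NormalizedTable,
    group_summary,
    module_score,
    overdispersion_test,
    score_collection,
)
from phosphodiff.roma import _pc1
from .conftest import build_design


def norm_table(values, design, genes=None):
    frame = pd.DataFrame(values, columns=design.samples)
    frame.index = [f"P{i:03d}" for i in range(len(frame))]
    genes = genes or [f"G{i:03d}" for i in range(len(frame))]
    return NormalizedTable(values=frame, design=design, layer="proteome", axis="sample",
                           gene_symbols=pd.Series(genes, index=frame.index))


class TestModuleScore:
    def test_rank_one_matrix_gives_L1_of_one(self, design4):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=12)
        loadings = rng.normal(size=5)
        values = np.outer(loadings, profile)
        norm = norm_table(values, design4)
        res = module_score(norm, "m", [f"G{i:03d}" for i in range(5)])
        assert res.L1 == pytest.approx(1.0)

    def test_closed_form_two_by_two_covariance(self):
        # gene x gene covariance [[2,1],[1,2]] -> eigenvalues 3,1 -> L1 = 0.75
        a = np.array([np.sqrt(2), 0.0, -np.sqrt(2)])
        c = np.array([1.0, -2.0, 1.0])
        b = 0.5 * a + np.sqrt(0.5) * c
        X = np.vstack([a, b])
        cov = X @ X.T / 2
        np.testing.assert_allclose(cov, [[2, 1], [1, 2]], atol=1e-12)
        _, L1, _ = _pc1(X)
        assert L1 == pytest.approx(0.75)

    def test_L1_matches_bruteforce_eigendecomposition(self, design4):
        rng = np.random.default_rng(1)
        for k in (3, 4, 6):
            X = rng.normal(size=(k, 12))
            _, L1, _ = _pc1(X)
            C = np.cov(X)
            evals = np.linalg.eigvalsh(C)
            assert L1 == pytest.approx(evals[-1] / evals.sum(), abs=1e-12)
            assert 1 / k - 1e-12 <= L1 <= 1 + 1e-12

    def test_weights_unit_norm_and_oriented(self, design4):
        rng = np.random.default_rng(2)
        values = np.outer(np.ones(4), np.linspace(-1, 1, 12)) + rng.normal(0, .05, (4, 12))
        norm = norm_table(values, design4)
        res = module_score(norm, "m", [f"G{i:03d}" for i in range(4)])
        assert np.linalg.norm(res.weights) == pytest.approx(1.0)
        # scores correlate positively with the mean expression profile
        mean_profile = norm.values.iloc[:4].mean(axis=0) - norm.values.iloc[:4].mean(axis=0).mean()
        assert np.dot(res.sample_scores, mean_profile) > 0

    def test_too_few_matched_genes_skipped(self, design4):
        norm = norm_table(np.random.default_rng(3).normal(size=(5, 12)), design4)
        assert module_score(norm, "m", ["G000", "G001"]) is None
        assert module_score(norm, "m", ["nope1", "nope2", "nope3"]) is None

    def test_genes_with_missing_samples_dropped(self, design4):
        values = np.random.default_rng(4).normal(size=(6, 12))
        values[0, 3] = np.nan
        norm = norm_table(values, design4)
        res = module_score(norm, "m", [f"G{i:03d}" for i in range(6)])
        assert "G000" not in res.genes_used and len(res.genes_used) == 5


class TestOverdispersion:
    def test_whole_universe_gives_p_one(self, design4):
        norm = norm_table(np.random.default_rng(5).normal(size=(10, 12)), design4)
        L1, p = overdispersion_test(norm, [f"G{i:03d}" for i in range(10)],
                                    n_null=50, seed=0)
        assert p == 1.0

    def test_unmatchable_set_skipped(self, design4):
        norm = norm_table(np.random.default_rng(6).normal(size=(4, 12)), design4)
        assert overdispersion_test(norm, ["absent1", "absent2", "absent3"],
                                   n_null=10, seed=0) is None

    def test_gene_order_invariance(self, design4):
        norm = norm_table(np.random.default_rng(7).normal(size=(30, 12)), design4)
        genes = [f"G{i:03d}" for i in range(8)]
        a = overdispersion_test(norm, genes, n_null=200, seed=1)
        b = overdispersion_test(norm, genes[::-1], n_null=200, seed=1)
        assert a == b

    def test_planted_latent_factor_detected(self, design4):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(100, 12)) * 0.6
        factor = rng.normal(size=12)
        values[:8] = 0.8 * factor[None, :] + 0.6 * rng.normal(size=(8, 12))
        norm = norm_table(values, design4)
        L1, p = overdispersion_test(norm, [f"G{i:03d}" for i in range(8)],
                                    n_null=500, seed=2)
        assert p <= 0.01


class TestGroupSummary:
    def make_results(self, design, scores_by_module):
        from phosphodiff import ModuleActivityResult
        out = []
        for name, scores in scores_by_module.items():
            out.append(ModuleActivityResult(
                name=name, genes_used=["a", "b", "c"],
                weights=pd.Series([1.0, 0, 0], index=["a", "b", "c"]),
                L1=0.5,
                sample_scores=pd.Series(scores, index=design.samples),
            ))
        return out

    def test_scaling_by_hand(self, design4):
        # CS mean 2, CR mean -4 -> scaled {0.5, -1}
        scores = np.zeros(12)
        scores[3:6] = 2.0
        scores[6:12] = -4.0
        results = self.make_results(design4, {"m": scores})
        table = group_summary(results, design4)
        assert table.loc["m", "CS"] == pytest.approx(0.5)
        assert table.loc["m", "CR"] == pytest.approx(-1.0)

    def test_equal_means_scale_to_unit(self, design4):
        scores = np.full(12, 3.0)
        table = group_summary(self.make_results(design4, {"m": scores}), design4)
        assert abs(table.loc["m", "CS"]) == 1.0
        assert table.loc["m", "CS"] == table.loc["m", "CR"]

    def test_empty_group_is_error(self):
        design = build_design({"A": "CS", "B": "benign"}, replicates=2)
        results = self.make_results(design, {"m": np.ones(4)})
        with pytest.raises(ConfigurationError, match="no samples"):
            group_summary(results, design)


def test_collection_scoring_flags_planted_module(default_run):
    from phosphodiff import log2_zscore, valid_value_filter, make_gene_sets

    cfg, prot, phos, truth = default_run
    kept, _ = valid_value_filter(prot)
    norm = log2_zscore(kept)
    sets = {name: truth.modules[name] for name in list(truth.modules)[:4]}
    results, table = score_collection(norm, sets, n_null=200, seed=3)
    table = table.set_index("module")
    assert bool(table.loc[truth.overdispersed_module, "overdispersed"])
    others = table.drop(index=truth.overdispersed_module)
    assert (others["p_overdispersion"] > 0.01).all()
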