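"""Capacity scoring, group ranking, trend correlation and module tests."""

import numpy as np
import pandas as pd
import pytest

from spermatocap import capacity as cap
from spermatocap import core, datasets
from tests.conftest import make_norm


@pytest.fixture(scope="module")
def ranked(default_norm, germ_cell_ids):
    sperm = datasets.load_spermatogenesis_set()
    return cap.rank_groups(
        cap.spermatogenesis_score(default_norm, sperm, germ_cell_ids))


class TestSpermScore:
    def test_cell_at_gene_means_scores_zero(self):
        vals = np.array([[0.0, 2.0, 4.0], [1.0, 2.0, 3.0]])
        norm = make_norm(vals, group=["A", "A", "B"])
        gs = core.GeneSet("s", "spermatogenesis", ("G0", "G1"))
        res = cap.spermatogenesis_score(norm, gs, list(norm.cell_ids))
        assert res.scores.iloc[1] == pytest.approx(0.0)

    def test_degenerate_constant_genes_error(self):
        norm = make_norm(np.full((2, 5), 3.0))
        gs = core.GeneSet("s", "spermatogenesis", ("G0", "G1"))
        with pytest.raises(ValueError, match="zero variance"):
            cap.spermatogenesis_score(norm, gs, list(norm.cell_ids))

    def test_shifted_group_median_difference(self):
        # group B shifted +1 on both set genes; z-scale shift = 1/sd per gene
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(2, 40))
        vals = base.copy()
        vals[:, 20:] += 1.0
        norm = make_norm(vals, group=["A"] * 20 + ["B"] * 20)
        gs = core.GeneSet("s", "spermatogenesis", ("G0", "G1"))
        res = cap.spermatogenesis_score(norm, gs, list(norm.cell_ids))
        med = res.summaries["median"]
        sd = vals.std(axis=1, ddof=1)
        # the two group medians differ by roughly the z-scaled shift
        assert med["B"] - med["A"] == pytest.approx(np.mean(1.0 / sd), abs=0.3)


class TestRankGroups:
    def test_three_group_order(self):
        rng = np.random.default_rng(1)
        vals = np.vstack([rng.normal(0, 1, 90) + np.repeat([2.0, 1.0, 0.0], 30)
                          for _ in range(3)])
        norm = make_norm(vals, group=np.repeat(["X", "Y", "Z"], 30))
        gs = core.GeneSet("s", "spermatogenesis", ("G0", "G1", "G2"))
        res = cap.rank_groups(cap.spermatogenesis_score(norm, gs, list(norm.cell_ids)))
        assert res.ranking == ("X", "Y", "Z")
        assert res.severity_rank == {"X": 1, "Y": 2, "Z": 3}

    def test_identical_groups_tie_noted(self):
        vals = np.tile(np.array([[0.0, 1.0, 2.0, 3.0]]), (2, 1))
        norm = make_norm(vals + np.random.default_rng(0).normal(0, 1e-9, vals.shape),
                         group=["A", "B", "A", "B"])
        gs = core.GeneSet("s", "spermatogenesis", ("G0", "G1"))
        res = cap.spermatogenesis_score(norm, gs, list(norm.cell_ids))
        res.summaries["median"] = pd.Series({"A": 0.5, "B": 0.5})
        res.summaries["n"] = pd.Series({"A": 2, "B": 2})
        ranked = cap.rank_groups(res)
        assert len(ranked.ranking) == 2
        assert ranked.ties == (("A", "B"),)

    def test_planted_severity_order_recovered(self, ranked, default_dataset):
        _, truth = default_dataset
        assert ranked.ranking == tuple(truth.config.severity_order)
        assert all(ranked.pairwise["p_value"] < 0.05)


class TestTrendCorrelations:
    def _toy_norm(self, donor_means, ranks):
        # one cell per donor so donor means equal the cell values
        donors = [f"d{i}" for i in range(len(donor_means))]
        vals = np.asarray([donor_means])
        norm = make_norm(vals, donor=donors,
                         group=[f"g{r}" for r in ranks])
        return norm, donors

    def _result_with_ranks(self, ranks):
        res = cap.CapacityResult(
            scores=pd.Series(dtype=float), group_of_cell=pd.Series(dtype=object),
            summaries=pd.DataFrame(), n_genes_used=0)
        res.severity_rank = {f"g{r}": r for r in sorted(set(ranks))}
        res.ranking = tuple(f"g{r}" for r in sorted(set(ranks)))
        return res

    @pytest.mark.parametrize("means,expected_rho", [
        ([1.0, 2.0, 3.0, 4.0, 5.0], 1.0),
        ([5.0, 4.0, 3.0, 2.0, 1.0], -1.0),
        ([1.0, 2.0, 3.0, 5.0, 4.0], 0.9),  # one swapped pair: 1 - 6*2/120
    ])
    def test_hand_spearman(self, means, expected_rho):
        ranks = [1, 2, 3, 4, 5]
        norm, donors = self._toy_norm(means, ranks)
        res = self._result_with_ranks(ranks)
        trends = cap.trend_correlations(norm, res, list(norm.cell_ids))
        assert trends.loc[0, "rho"] == pytest.approx(expected_rho)

    def test_invariant_under_monotone_rank_transform(self):
        means = [1.0, 3.0, 2.0, 5.0, 4.0]
        norm, _ = self._toy_norm(means, [1, 2, 3, 4, 5])
        res1 = self._result_with_ranks([1, 2, 3, 4, 5])
        t1 = cap.trend_correlations(norm, res1, list(norm.cell_ids))
        res2 = self._result_with_ranks([1, 2, 3, 4, 5])
        res2.severity_rank = {f"g{r}": r ** 3 + 10 for r in [1, 2, 3, 4, 5]}
        t2 = cap.trend_correlations(norm, res2, list(norm.cell_ids))
        assert t1.loc[0, "rho"] == pytest.approx(t2.loc[0, "rho"])

    def test_requires_rank_spread(self):
        norm, _ = self._toy_norm([1.0, 2.0, 3.0], [1, 1, 2])
        res = self._result_with_ranks([1, 1, 2])
        with pytest.raises(ValueError, match="donors"):
            cap.trend_correlations(norm, res, list(norm.cell_ids))

    def test_planted_trend_auroc(self, default_norm, germ_cell_ids, ranked,
                                 default_dataset):
        from sklearn.metrics import roc_auc_score
        _, truth = default_dataset
        trends = cap.trend_correlations(default_norm, ranked, germ_cell_ids)
        planted = set(truth.trend_genes["gene"])
        structured = set(truth.structured_genes["gene"])
        # positives: the 50 planted monotone genes; negatives: genes with no
        # planted group structure of any kind
        ev = trends[trends["gene"].isin(planted) | ~trends["gene"].isin(structured)]
        auroc = roc_auc_score(ev["gene"].isin(planted), ev["rho"].abs())
        assert auroc >= 0.9


class TestTrendModules:
    def test_two_archetypes_perfectly_split(self):
        up = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        down = up[::-1]
        genes = [f"U{i}" for i in range(5)] + [f"D{i}" for i in range(5)]
        profiles = pd.DataFrame(
            np.vstack([np.tile(up, (5, 1)) * (1 + 0.1 * np.arange(5))[:, None],
                       np.tile(down, (5, 1)) * (1 + 0.1 * np.arange(5))[:, None]]),
            index=pd.Index(genes, name="gene"))
        trends = pd.DataFrame({
            "gene": genes,
            "rho": [1.0] * 5 + [-1.0] * 5,
            "p_value": 1e-6, "p_adjusted": 1e-5,
        })
        out = cap.trend_modules(trends, profiles, m=2, seed=0).set_index("gene")
        assert set(out.loc[[f"U{i}" for i in range(5)], "module"]) == {1}
        assert set(out.loc[[f"D{i}" for i in range(5)], "module"]) == {2}

    def test_same_seed_same_modules(self, default_norm, germ_cell_ids, ranked):
        trends = cap.trend_correlations(default_norm, ranked, germ_cell_ids)
        sig = trends[trends["p_adjusted"] < 0.05]
        profiles = cap.group_mean_profiles(default_norm, germ_cell_ids, ranked.ranking)
        m1 = cap.trend_modules(sig, profiles, m=5, seed=3)
        m2 = cap.trend_modules(sig, profiles, m=5, seed=3)
        assert m1["module"].tolist() == m2["module"].tolist()

    def test_end_modules_capture_planted_genes(self, default_norm, germ_cell_ids,
                                               ranked, default_dataset):
        _, truth = default_dataset
        trends = cap.trend_correlations(default_norm, ranked, germ_cell_ids)
        sig = trends[trends["p_adjusted"] < 0.05]
        profiles = cap.group_mean_profiles(default_norm, germ_cell_ids, ranked.ranking)
        modules = cap.trend_modules(sig, profiles, m=5, seed=0)
        planted = modules[modules["gene"].isin(set(truth.trend_genes["gene"]))]
        assert len(planted) >= 45  # nearly all planted genes are significant
        assert planted["module"].isin([1, 5]).mean() >= 0.9


class TestExternalOverlap:
    def _modules(self):
        return pd.DataFrame({
            "gene": ["A", "B", "C", "X", "Y", "Z"],
            "rho": [0.9, 0.9, 0.9, -0.9, -0.9, -0.9],
            "p_value": 0.001, "p_adjusted": 0.01,
            "module": [1, 1, 1, 5, 5, 5],
        })

    def test_set_arithmetic(self):
        ext = pd.DataFrame({
            "list_name": ["ks"] * 4 + ["azf"] * 2,
            "gene": ["B", "C", "D", "Y", "X", "Q"],
            "direction": ["up", "up", "up", "down", "down", "down"],
        })
        out = cap.external_overlap(self._modules(), ext)
        out = out.set_index(["module", "list_name"])
        assert out.loc[(1, "ks"), "n_overlap"] == 2
        assert out.loc[(1, "ks"), "genes"] == "B,C"
        assert out.loc[(5, "azf"), "n_overlap"] == 1

    def test_disjoint_and_identical(self):
        mods = self._modules()
        ext_disjoint = pd.DataFrame({
            "list_name": ["l1"] * 2, "gene": ["Q", "R"], "direction": ["up", "up"]})
        assert cap.external_overlap(mods, ext_disjoint)["n_overlap"].tolist()[0] == 0
        ext_same = pd.DataFrame({
            "list_name": ["l2"] * 3, "gene": ["A", "B", "C"], "direction": ["up"] * 3})
        out = cap.external_overlap(mods, ext_same).set_index("module")
        assert out.loc[1, "n_overlap"] == 3
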