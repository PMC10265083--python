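"""Unit and property tests for the core container, QC, normalization and
shared statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse
from hypothesis import given, settings, strategies as st

from spermatocap import core
from tests.conftest import make_norm


def small_matrix(counts, genes, cells, donor="d1", group="NC"):
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["donor"] = donor
    meta["group"] = group
    return core.CellMatrix(
        counts=scipy.sparse.csr_matrix(np.asarray(counts)),
        gene_symbols=np.asarray(genes, dtype=object),
        cell_ids=np.asarray(cells, dtype=object),
        cell_meta=meta,
    )


class TestCellMatrix:
    def test_gene_flags_from_symbol_prefixes(self):
        m = small_matrix([[1], [2], [3], [4]], ["MT-CO1", "RPS6", "RPL3", "DDX4"], ["c0"])
        assert m.gene_flags["mitochondrial"].tolist() == [True, False, False, False]
        assert m.gene_flags["ribosomal"].tolist() == [False, True, True, False]

    def test_duplicate_symbols_rejected_case_insensitively(self):
        with pytest.raises(core.LoadError, match="duplicate"):
            small_matrix([[1], [2]], ["ddx4", "DDX4"], ["c0"])

    def test_dimension_mismatch_named(self):
        with pytest.raises(core.LoadError, match="dimension mismatch"):
            small_matrix([[1, 2]], ["A"], ["c0"])


class TestLoadCounts:
    def test_dense_tsv_matches_file_cell_by_cell(self, tmp_path):
        # 3 genes x 2 cells toy, values hand-read from the written file
        path = tmp_path / "toy.tsv"
        path.write_text("gene\tc1\tc2\nA\t5\t0\nB\t1\t2\nC\t0\t7\n")
        m = core.load_counts(path, format="tsv")
        dense = np.asarray(m.counts.todense())
        assert dense.tolist() == [[5, 0], [1, 2], [0, 7]]
        assert list(m.gene_symbols) == ["A", "B", "C"]
        assert list(m.cell_ids) == ["c1", "c2"]


class TestQCFilter:
    def _matrix_with(self, n_genes_detected, total):
        # one cell expressing `n_genes_detected` genes summing to `total`
        n = 3000
        counts = np.zeros((n, 1), dtype=np.int64)
        counts[: n_genes_detected, 0] = 1
        counts[0, 0] += total - n_genes_detected
        return small_matrix(counts, [f"G{i}" for i in range(n)], ["c0"])

    @pytest.mark.parametrize(
        "detected,total,kept",
        [
            (2000, 20000, False),  # boundary: exactly 2000 genes is NOT enough
            (2001, 10001, True),   # strictly above both thresholds
            (2500, 10000, False),  # exactly 10000 transcripts is NOT enough
        ],
    )
    def test_strict_inequalities_at_boundaries(self, detected, total, kept):
        m = self._matrix_with(detected, total)
        filtered, report = core.qc_filter(m)
        assert (filtered.n_cells == 1) is kept
        assert report["retained"].iloc[0] is np.bool_(kept)

    def test_idempotent(self, default_dataset):
        matrix, _ = default_dataset
        once, _ = core.qc_filter(matrix, min_genes=900, min_transcripts=9000)
        twice, _ = core.qc_filter(once, min_genes=900, min_transcripts=9000)
        assert twice.n_cells == once.n_cells
        assert (twice.counts != once.counts).nnz == 0


class TestNormalize:
    def test_spot_values(self):
        # cell with counts {A: 90, B: 10}: TPM A = 900000 -> log2(90001)
        m = small_matrix([[90], [10]], ["A", "B"], ["c0"])
        norm = core.normalize(m, exclude_flags=())
        assert norm.values[0, 0] == pytest.approx(math.log2(90001))
        assert norm.values[1, 0] == pytest.approx(math.log2(10001))

    def test_zero_count_gives_zero_and_tpm10_gives_one(self):
        # a gene at TPM 10 maps to exactly 1; a zero count maps to exactly 0
        m = small_matrix([[1], [99999], [0]], ["A", "B", "C"], ["c0"])
        norm = core.normalize(m, exclude_flags=())
        assert norm.values[0, 0] == pytest.approx(1.0)  # 1/100000 * 1e6 = TPM 10
        assert norm.values[2, 0] == 0.0

    def test_excluded_genes_dropped_before_rescaling(self):
        m = small_matrix([[50], [50]], ["MT-CO1", "A"], ["c0"])
        norm = core.normalize(m)
        assert list(norm.gene_symbols) == ["A"]
        # A carries the whole library after exclusion: TPM 1e6
        assert norm.values[0, 0] == pytest.approx(math.log2(1e5 + 1))

    def test_tpm_conserved_per_cell(self, default_dataset):
        matrix, _ = default_dataset
        sub = matrix.subset_cells(np.arange(64))
        norm = core.normalize(sub)
        tpm = (2.0 ** norm.values - 1.0) * 10.0
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_cell_is_an_error_naming_it(self):
        m = small_matrix([[5, 0], [3, 0]], ["A", "B"], ["c0", "empty"])
        with pytest.raises(ValueError, match="empty"):
            core.normalize(m, exclude_flags=())


class TestGeneSetZscore:
    def test_two_cell_single_gene(self):
        # values {0, 2}: sample sd sqrt(2) -> z = -/+ 1/sqrt(2)
        norm = make_norm([[0.0, 2.0]], genes=["A"])
        s, n_used = core.gene_set_zscore(norm, core.GeneSet("t", "custom", ("A",)))
        assert n_used == 1
        assert s.tolist() == pytest.approx([-0.70710678, 0.70710678])

    def test_cell_at_gene_means_scores_zero(self):
        norm = make_norm([[0.0, 1.0, 2.0], [3.0, 5.0, 7.0]])
        s, _ = core.gene_set_zscore(norm, core.GeneSet("t", "custom", ("G0", "G1")))
        assert s.iloc[1] == pytest.approx(0.0)

    def test_absent_set_is_an_error(self):
        norm = make_norm([[0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            core.gene_set_zscore(norm, core.GeneSet("missing", "custom", ("NOPE",)))

    def test_full_universe_scores_average_to_zero(self, default_norm):
        full = core.GeneSet("all", "custom", tuple(default_norm.gene_symbols[:500]))
        cells = list(default_norm.cell_ids[:200])
        s, _ = core.gene_set_zscore(default_norm, full, cells)
        assert abs(s.mean()) < 1e-9


def exact_wilcoxon_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(combo)]
        g2 = np.delete(pooled, list(combo))
        us.append(sum(1 for a in g1 for b in g2 if a > b))
    us = np.asarray(us)
    p_ge = (us >= u_obs).mean()
    p_le = (us <= u_obs).mean()
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        res = core.wilcoxon_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert res.effect == 0.0

    def test_separated_triples_exact_p(self):
        # all group-1 values below group-2: U = 0, exact two-sided p = 2/20
        res = core.wilcoxon_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.effect == pytest.approx(-3.0)

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, min(6, 11 - n1)))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = core.wilcoxon_test(x, y)
            assert res.p_value == pytest.approx(exact_wilcoxon_oracle(x, y))

    def test_null_rejection_rate_is_calibrated(self):
        # iid groups: rejection at alpha=0.05 should sit near 0.05
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            if core.wilcoxon_test(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


def chisq_oracle(table):
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return ((table - expected) ** 2 / expected).sum()


class TestChisq:
    def test_uniform_table_statistic_zero(self):
        res = core.chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # n(ad-bc)^2 / (row & col products) = 60*300^2/810000 = 6.6667
        res = core.chisq_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(1, 50), min_size=2, max_size=4),
            min_size=2, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_statistic_matches_textbook_oracle(self, rows):
        res = core.chisq_test(rows)
        assert res.statistic == pytest.approx(chisq_oracle(rows))

    def test_zero_marginal_is_an_error(self):
        with pytest.raises(ValueError, match="column"):
            core.chisq_test([[1, 0], [2, 0]])
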