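"""QC filters, normalization, HVG selection, tensor build and integration."""

import numpy as np
import pandas as pd
import pytest

from isoplex import (
    CellMetadata,
    CountMatrix,
    QCParams,
    build_scht,
    create_scht,
    filter_cells,
    filter_features,
    integrate_cell_types,
    load_scht,
    normalize,
    recommend_qc_parameters,
    save_scht,
    select_hvgs,
)
from isoplex.scht import PipelineError


class TestRecommendQcParameters:
    def test_percentile_bounds(self, rng):
        counts = (rng.random((300, 100)) < rng.uniform(0.2, 0.8, size=(300, 1))).astype(float)
        m = CountMatrix.from_dense(counts, [f"g{i}" for i in range(300)], [f"c{i}" for i in range(100)])
        gpc = (counts > 0).sum(axis=0)
        p = recommend_qc_parameters(m)
        assert p.n_min <= np.percentile(gpc, 1)
        assert p.n_max >= np.percentile(gpc, 99)

    def test_degenerate_distribution_returns_defaults(self):
        counts = np.ones((500, 50))
        m = CountMatrix.from_dense(counts, [f"g{i}" for i in range(500)], [f"c{i}" for i in range(50)])
        p = recommend_qc_parameters(m)
        assert (p.n_min, p.n_max) == (200, 20000)
        assert p.n_min < 500 < p.n_max

    def test_few_cells_warns_and_defaults(self):
        m = CountMatrix.from_dense(np.ones((10, 5)), [f"g{i}" for i in range(10)], [f"c{i}" for i in range(5)])
        with pytest.warns(UserWarning):
            p = recommend_qc_parameters(m)
        assert (p.n_min, p.n_max) == (200, 20000)


def _paired(counts_gene, info, iso_counts=None):
    n_c = counts_gene.shape[1]
    cells = [f"c{i}" for i in range(n_c)]
    gene = CountMatrix.from_dense(counts_gene, [f"g{i}" for i in range(counts_gene.shape[0])], cells)
    iso_counts = counts_gene if iso_counts is None else iso_counts
    iso = CountMatrix.from_dense(iso_counts, [f"g{i}-I1" for i in range(iso_counts.shape[0])], cells)
    return gene, iso


class TestFilterFeatures:
    @pytest.fixture()
    def info2(self):
        from isoplex import TranscriptInfo

        n = 3
        return TranscriptInfo(
            pd.DataFrame(
                {
                    "transcript_id": [f"g{i}-I1" for i in range(n)],
                    "gene_id": [f"g{i}" for i in range(n)],
                    "gene_name": [f"g{i}" for i in range(n)],
                }
            )
        )

    def test_low_detection_removed(self, info2):
        counts = np.zeros((3, 100))
        counts[0, 0] = 5            # detected in 1/100 < p_min=0.02
        counts[1, :50] = 1
        counts[2, :] = 2
        gene, iso = _paired(counts, info2)
        g2, i2 = filter_features(gene, iso, QCParams(), info2)
        assert "g0" not in g2.features
        assert {"g1", "g2"} <= set(g2.features)

    def test_mean_floor_removed(self, info2):
        counts = np.zeros((3, 100))
        counts[0, :5] = 1e-3        # mean 5e-5 < eps, detection 5% > p_min
        counts[1, :50] = 1
        counts[2, :] = 2
        gene, iso = _paired(counts, info2)
        g2, _ = filter_features(gene, iso, QCParams(), info2)
        assert "g0" not in g2.features

    def test_isoforms_of_retained_genes_kept(self, tiny_iso_matrix, tiny_info):
        from isoplex import aggregate_gene_counts

        gene = aggregate_gene_counts(tiny_iso_matrix, tiny_info)
        g2, i2 = filter_features(gene, tiny_iso_matrix, QCParams(p_min=0.3), tiny_info)
        # GB retained -> its weakly expressed isoform GB-I3 (1 cell of 8) kept
        assert "GB-I3" in i2.features

    def test_nothing_survives_is_error(self, info2):
        counts = np.zeros((3, 100))
        counts[:, 0] = 1
        gene, iso = _paired(counts, info2)
        with pytest.raises(PipelineError):
            filter_features(gene, iso, QCParams(p_min=0.5), info2)


class TestFilterCells:
    def test_bounds_inclusive_and_loop_oracle(self, rng):
        counts = (rng.random((30, 50)) < 0.4).astype(float)
        cells = [f"c{i}" for i in range(50)]
        gene = CountMatrix.from_dense(counts, [f"g{i}" for i in range(30)], cells)
        iso = CountMatrix.from_dense(counts, [f"t{i}" for i in range(30)], cells)
        params = QCParams(n_min=10, n_max=15)
        g2, i2 = filter_cells(gene, iso, params)
        expected = [c for j, c in enumerate(cells) if 10 <= (counts[:, j] > 0).sum() <= 15]
        assert list(g2.cells) == expected
        assert list(i2.cells) == expected

    def test_boundary_cell_retained(self):
        counts = np.zeros((300, 3))
        counts[:150, 0] = 1   # exactly n_min detected genes
        counts[:149, 1] = 1   # one below
        counts[:200, 2] = 1
        gene = CountMatrix.from_dense(counts, [f"g{i}" for i in range(300)], ["a", "b", "c"])
        iso = CountMatrix.from_dense(counts, [f"t{i}" for i in range(300)], ["a", "b", "c"])
        g2, _ = filter_cells(gene, iso, QCParams(n_min=150, n_max=20000))
        assert list(g2.cells) == ["a", "c"]


class TestNormalize:
    def test_cpm_lognorm_closed_form(self):
        m = CountMatrix.from_dense(np.array([[5.0], [0.0]]), ["g1", "g2"], ["c1"])
        out = normalize(m, "raw_counts")
        assert out.layer_tag == "lognorm"
        assert out.to_dense()[0, 0] == pytest.approx(np.log2(1e6 + 1), abs=1e-9)
        assert out.to_dense()[1, 0] == 0.0

    def test_pre_normalized_log_only(self):
        m = CountMatrix.from_dense(np.array([[3.0]]), ["g1"], ["c1"], layer_tag="normalised")
        out = normalize(m, "normalised")
        assert out.to_dense()[0, 0] == pytest.approx(2.0)

    def test_per_cell_scale_invariance(self, rng):
        counts = rng.poisson(3.0, size=(20, 10)).astype(float)
        scale = rng.uniform(0.5, 8.0, size=10)
        a = normalize(CountMatrix.from_dense(counts, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(10)]), "raw_counts")
        b = normalize(
            CountMatrix.from_dense(counts * scale, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(10)]),
            "raw_counts",
        )
        np.testing.assert_allclose(a.to_dense(), b.to_dense(), atol=1e-9)

    def test_zero_column_maps_to_zero(self):
        counts = np.array([[1.0, 0.0], [2.0, 0.0]])
        out = normalize(CountMatrix.from_dense(counts, ["g1", "g2"], ["c1", "c2"]), "raw_counts")
        assert out.to_dense()[:, 1].sum() == 0.0


class TestSelectHvgs:
    def test_matches_bruteforce_dispersion_ranking(self, rng):
        counts = rng.poisson(rng.uniform(0.5, 20, size=(50, 1)), size=(50, 40)).astype(float)
        m = normalize(
            CountMatrix.from_dense(counts, [f"g{i:02d}" for i in range(50)], [f"c{i}" for i in range(40)]),
            "raw_counts",
        )
        hvgs = select_hvgs(m, 10)
        X = m.to_dense()
        disp = {}
        for i, g in enumerate(m.features):
            mu = X[i].mean()
            if mu > 0:
                disp[g] = X[i].var(ddof=1) / mu
        expected = sorted(disp, key=lambda g: (-disp[g], -X[list(m.features).index(g)].mean(), g))[:10]
        assert hvgs == expected

    def test_constant_gene_ranked_last(self):
        X = np.array([[1.0] * 6, [0, 5, 0, 9, 1, 2]])
        m = CountMatrix.from_dense(X, ["const", "var"], [f"c{i}" for i in range(6)], layer_tag="normalised")
        m = normalize(m, "normalised")
        assert select_hvgs(m, 2) == ["var", "const"]

    def test_n_hvg_capped(self, quadrants_run):
        # requested 3000 but only the dataset's genes exist
        assert quadrants_run["run_log"]["hvg"]["n_hvg_selected"] <= 3000


class TestBuildAndIntegrate:
    def test_single_isoform_genes_dropped_and_counted(self, tiny_iso_matrix, tiny_info):
        norm = normalize(tiny_iso_matrix, "raw_counts")
        from isoplex.scht import RunLog

        log = RunLog()
        scht = build_scht(norm, tiny_info, ["GA", "GB", "GC"], log)
        assert set(scht.genes) == {"GA", "GB"}
        assert log["scht"]["genes_single_isoform_removed"] == 1

    def test_submatrix_shapes(self, tiny_iso_matrix, tiny_info):
        norm = normalize(tiny_iso_matrix, "raw_counts")
        scht = build_scht(norm, tiny_info, ["GA", "GB"])
        assert scht.matrices["GA"].shape == (2, 8)
        assert scht.matrices["GB"].shape == (3, 8)

    def test_nonzero_identity(self, quadrants_run):
        scht = quadrants_run["scht"]
        assert quadrants_run["run_log"]["sparsity"]["nonzero_elements"] == scht.total_nonzero()

    def test_integration_matches_bruteforce(self, rng, tiny_iso_matrix, tiny_info, tiny_meta):
        norm = normalize(tiny_iso_matrix, "raw_counts")
        scht = build_scht(norm, tiny_info, ["GA", "GB"])
        ischt = integrate_cell_types(scht, tiny_meta)
        X = scht.matrices["GB"]
        for k, type_cells in (("T0", [0, 1, 2, 3]), ("T1", [4, 5, 6, 7])):
            cols = [j for j in type_cells if X[:, j].sum() > 0]
            rows = [i for i in range(3) if X[np.ix_([i], cols)].sum() > 0]
            entry = ischt.by_type["GB"][k]
            np.testing.assert_allclose(entry["X"], X[np.ix_(rows, cols)])
            assert list(entry["cells"]) == [f"c{j}" for j in cols]

    def test_single_type_partition_is_identity(self, tiny_iso_matrix, tiny_info):
        norm = normalize(tiny_iso_matrix, "raw_counts")
        scht = build_scht(norm, tiny_info, ["GA", "GB"])
        meta = CellMetadata(pd.Series(["T0"] * 8, index=scht.cells))
        ischt = integrate_cell_types(scht, meta)
        for g in scht.genes:
            X = scht.matrices[g]
            expressing = X.sum(axis=0) > 0
            entry = ischt.by_type[g]["T0"]
            np.testing.assert_allclose(entry["X"], X[:, expressing])

    def test_unannotated_cells_error(self, tiny_iso_matrix, tiny_info):
        norm = normalize(tiny_iso_matrix, "raw_counts")
        scht = build_scht(norm, tiny_info, ["GA"])
        meta = CellMetadata(pd.Series(["T0"] * 4, index=[f"c{i}" for i in range(4)]))
        with pytest.raises(ValueError, match="annotation"):
            integrate_cell_types(scht, meta)

    def test_typed_submatrices_tile_expressing_cells(self, quadrants_run):
        ischt = quadrants_run["scht"]
        for g in list(ischt.genes)[:10]:
            X = ischt.matrices[g]
            expressing = set(np.asarray(ischt.cells)[X.sum(axis=0) > 0])
            typed = set()
            for entry in ischt.by_type[g].values():
                typed |= set(entry["cells"])
            assert typed == expressing


class TestSerialization:
    def test_roundtrip(self, tmp_path, quadrants_run):
        scht = quadrants_run["scht"]
        save_scht(scht, tmp_path / "scht")
        back = load_scht(tmp_path / "scht")
        assert set(back.genes) == set(scht.genes)
        g = scht.genes[0]
        np.testing.assert_allclose(back.matrices[g], scht.matrices[g], atol=1e-12)
        assert back.isoforms[g] == scht.isoforms[g]
        assert set(back.by_type[g]) == set(scht.by_type[g])
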