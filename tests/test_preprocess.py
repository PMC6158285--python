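import numpy as np
import pytest

from fragstatis.preprocess import (AccessionTable, EmptyResultError,
                                   StructuralError, build_statis_tables,
                                   filter_missing, impute_bpca)

from conftest import make_dataset, quiet_config
from fragstatis.synthetic import generate_dataset


def _dataset_with_missing(missing_counts, n=10):
    """n samples × metabolites, column j missing missing_counts[j] cells."""
    p = len(missing_counts)
    vals = np.ones((n, p)) * 2.0
    for j, k in enumerate(missing_counts):
        vals[:k, j] = np.nan
    return make_dataset(vals)


class TestFilterMissing:
    def test_no_missing_is_unchanged(self):
        ds = make_dataset(np.ones((6, 3)))
        out, report = filter_missing(ds)
        assert out.equals(ds)
        assert not report["removed"].any()

    def test_strictly_greater_than_rule(self):
        # 3/10 = 30% removed; 2/10 = 20% retained (boundary); 1/10 retained
        ds = _dataset_with_missing([3, 2, 1], n=10)
        out, report = filter_missing(ds, 0.20)
        assert out.metabolite_ids == ["m2", "m3"]
        assert report.set_index("metabolite_id")["removed"].tolist() == \
            [True, False, False]

    def test_idempotent(self):
        ds = _dataset_with_missing([3, 2, 1], n=10)
        once, _ = filter_missing(ds)
        twice, _ = filter_missing(once)
        assert twice.equals(once)

    def test_all_removed_raises(self):
        ds = _dataset_with_missing([5, 6], n=10)
        with pytest.raises(EmptyResultError):
            filter_missing(ds, 0.20)

    def test_study_attrition_39_primary_81_secondary(self, default_dataset):
        ds, _ = default_dataset
        out, _ = filter_missing(ds)
        classes = out.metabolites["met_class"].value_counts()
        assert classes["primary"] == 39
        assert classes["secondary"] == 81


class TestImputeBPCA:
    def test_complete_dataset_unchanged(self):
        ds = make_dataset(np.abs(np.random.default_rng(0).normal(
            3, 1, size=(12, 5))))
        out, report = impute_bpca(ds, seed=0)
        assert np.allclose(out.values, ds.values, atol=1e-12)
        assert report["n_imputed"] == 0

    def test_output_has_no_missing_and_observed_unchanged(self):
        rng = np.random.default_rng(1)
        vals = 10.0 ** rng.normal(3, 0.5, size=(15, 8))
        mask = rng.random((15, 8)) < 0.1
        vals_m = vals.copy()
        vals_m[mask] = np.nan
        ds = make_dataset(vals_m)
        out, _ = impute_bpca(ds, seed=2)
        arr = out.values.to_numpy()
        assert not np.isnan(arr).any()
        assert np.array_equal(arr[~mask], vals[~mask])

    def test_beats_column_mean_on_low_rank_data(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(60, 2)) @ rng.normal(size=(2, 40))
        X = 10.0 ** (0.25 * L + 0.05 * rng.normal(size=(60, 40)) + 3)
        mask = rng.random((60, 40)) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        ds = make_dataset(Xm)
        out, report = impute_bpca(ds, n_components=5, seed=4)
        est = np.log10(out.values.to_numpy()[mask])
        truth = np.log10(X[mask])
        col_mean = np.nanmean(np.log10(Xm), axis=0)
        base = np.take(col_mean, np.nonzero(mask)[1])
        assert np.sqrt(np.mean((est - truth) ** 2)) < \
            np.sqrt(np.mean((base - truth) ** 2))


class TestStatisTables:
    def test_study_design_yields_14_tables_3x130(self, default_dataset):
        ds, _ = default_dataset
        tables = build_statis_tables(ds)
        assert len(tables) == 14
        for tb in tables:
            assert tb.X.shape == (3, 130)
            assert abs(tb.masses.sum() - 1.0) < 1e-12

    def test_columns_centered_and_cross_product_normalized(self,
                                                           default_dataset):
        ds, _ = default_dataset
        for tb in build_statis_tables(ds):
            assert np.abs(tb.X.sum(axis=0)).max() < 1e-10
            assert abs(np.linalg.norm(tb.X @ tb.X.T) - 1.0) < 1e-10

    def test_invariant_to_sample_order(self, default_dataset):
        ds, _ = default_dataset
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = ds.subset_samples(np.array(ds.sample_ids)[perm])
        t1 = {t.accession: t.X for t in build_statis_tables(ds)}
        t2 = {t.accession: t.X for t in build_statis_tables(shuffled)}
        for acc in t1:
            assert np.allclose(t1[acc], t2[acc], atol=1e-12)

    def test_stage_by_rep_mode(self, default_dataset):
        ds, _ = default_dataset
        tables = build_statis_tables(ds, row_mode="stage_by_rep")
        assert all(tb.X.shape == (9, 130) for tb in tables)

    def test_missing_stage_is_structural_error(self):
        vals = np.ones((4, 2))
        ds = make_dataset(vals, accessions=["A1"] * 3 + ["A2"],
                          stages=["G", "W", "R", "G"])
        with pytest.raises(StructuralError, match="A2"):
            build_statis_tables(ds)

    def test_masses_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AccessionTable("a", "D", ["G"], ["m1"], np.zeros((1, 1)),
                           np.array([0.5]))
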