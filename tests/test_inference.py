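"""Covariate inference: age, sex, genetic noise, LUMP, deconvolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methworks as mw
from methworks.errors import DataError
from methworks.inference import AgeModel, SexModel


def _dataset(betas, chroms=None, positions=None, snp_probe=None, coverage=None,
             samples=None, platform="synthetic"):
    betas = np.asarray(betas, float)
    n = betas.shape[0]
    chroms = chroms if chroms is not None else ["chr1"] * n
    positions = positions if positions is not None else list(range(1, n + 1))
    sites = mw.make_site_table(
        chroms, positions, "*",
        is_snp_probe=snp_probe if snp_probe is not None else False,
    )
    # realign matrices to the sorted site order
    raw = pd.Index([f"{c}:{p}:*" for c, p in zip(chroms, positions)])
    order = raw.get_indexer(sites.index)
    betas = betas[order]
    if coverage is not None:
        coverage = np.asarray(coverage, float)[order]
    if samples is None:
        samples = pd.DataFrame(
            index=pd.Index([f"s{j}" for j in range(betas.shape[1])], name="sample_id")
        )
    return mw.MethylationDataset(
        sites=sites, samples=samples, beta=betas, coverage=coverage, platform=platform
    )


class TestAgeModel:
    def test_prediction_linear_rule(self):
        model = AgeModel(
            intercept=10.0,
            coefficients=pd.Series({"chr1:1:*": 5.0}),
            training_site_means=pd.Series({"chr1:1:*": 0.6}),
            alpha=0.5, lam=0.1,
        )
        ds = _dataset([[0.4]])
        out = mw.predict_age(model, ds)
        assert out["predicted_age"].iloc[0] == pytest.approx(12.0)
        assert out["n_substituted"].iloc[0] == 0

    def test_absent_site_substituted_by_training_mean(self):
        model = AgeModel(
            intercept=10.0,
            coefficients=pd.Series({"chr9:999:*": 5.0}),
            training_site_means=pd.Series({"chr9:999:*": 0.6}),
            alpha=0.5, lam=0.1,
        )
        ds = _dataset([[0.4]])
        out = mw.predict_age(model, ds, min_overlap=0.0)
        assert out["predicted_age"].iloc[0] == pytest.approx(13.0)
        assert out["n_substituted"].iloc[0] == 1

    def test_all_sites_missing_gives_constant_prediction(self):
        model = AgeModel(
            intercept=1.0,
            coefficients=pd.Series({"chrZ:1:*": 2.0, "chrZ:2:*": 4.0}),
            training_site_means=pd.Series({"chrZ:1:*": 0.5, "chrZ:2:*": 0.25}),
            alpha=0.5, lam=0.1,
        )
        ds = _dataset(np.full((3, 4), 0.5))
        out = mw.predict_age(model, ds, min_overlap=0.0)
        expected = 1.0 + 2.0 * 0.5 + 4.0 * 0.25
        np.testing.assert_allclose(out["predicted_age"], expected)
        assert (out["n_substituted"] == 2).all()

    def test_low_overlap_errors(self):
        model = AgeModel(
            intercept=0.0,
            coefficients=pd.Series({"chrZ:1:*": 1.0, "chr1:1:*": 1.0}),
            training_site_means=pd.Series({"chrZ:1:*": 0.5, "chr1:1:*": 0.5}),
            alpha=0.5, lam=0.1,
        )
        ds = _dataset([[0.5]])
        with pytest.raises(DataError, match="model CpGs present"):
            mw.predict_age(model, ds, min_overlap=0.9)

    def test_noiseless_small_penalty_recovers_linear_truth(self):
        ds, ages, causal = mw.simulate_age_cohort(
            n_samples=60, n_sites=40, n_causal=4, noise_sd=0.0, seed=2
        )
        model = mw.train_age_model(ds, lambda_grid=[1e-6], cv_folds=4, seed=0)
        pred = mw.predict_age(model, ds)
        np.testing.assert_allclose(pred["predicted_age"], ages, atol=0.1)

    def test_in_sample_consistency_and_serialization_round_trip(self, tmp_path):
        ds, ages, _ = mw.simulate_age_cohort(n_samples=50, n_sites=60, seed=4)
        model = mw.train_age_model(ds, lambda_grid=[1e-3, 1e-2], cv_folds=4, seed=0)
        pred = mw.predict_age(model, ds)
        # the linear-rule prediction reproduces the fit's in-sample prediction
        X = ds.beta_frame().T
        manual = model.intercept + X[model.coefficients.index] @ model.coefficients
        np.testing.assert_allclose(pred["predicted_age"], manual, atol=1e-10)
        model.to_tsv(tmp_path / "age.tsv")
        back = AgeModel.from_tsv(tmp_path / "age.tsv")
        pd.testing.assert_series_equal(
            back.coefficients, model.coefficients, check_names=False
        )
        assert back.intercept == model.intercept and back.lam == model.lam

    def test_sample_permutation_leaves_model_unchanged(self):
        ds, ages, _ = mw.simulate_age_cohort(n_samples=40, n_sites=50, seed=6)
        model = mw.train_age_model(ds, lambda_grid=[1e-3, 1e-2, 1e-1], cv_folds=4, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_samples)
        ds_p = mw.MethylationDataset(
            sites=ds.sites, samples=ds.samples.iloc[perm], beta=ds.beta[:, perm],
            platform=ds.platform,
        )
        model_p = mw.train_age_model(ds_p, lambda_grid=[1e-3, 1e-2, 1e-1], cv_folds=4, seed=0)
        assert model_p.lam == model.lam
        pd.testing.assert_series_equal(model_p.coefficients, model.coefficients)

    def test_constant_age_errors(self):
        ds, _, _ = mw.simulate_age_cohort(n_samples=20, n_sites=30, seed=1)
        with pytest.raises(DataError, match="constant"):
            mw.train_age_model(ds, ages=np.full(20, 50.0))


class TestSexFeatures:
    def _cov_dataset(self, auto, x, y, n_each=10):
        n = 3 * n_each
        chroms = ["chr1"] * n_each + ["chrX"] * n_each + ["chrY"] * n_each
        cov = np.concatenate(
            [np.full((n_each, 1), auto), np.full((n_each, 1), x), np.full((n_each, 1), y)]
        )
        betas = np.where(cov > 0, 0.5, np.nan)
        return _dataset(betas, chroms=chroms, positions=list(range(1, n_each + 1)) * 3,
                        coverage=cov, platform="rrbs")

    def test_equal_coverage_gives_zero_ratios(self):
        ds = self._cov_dataset(30, 30, 30)
        f = mw.sex_features(ds)
        assert f["fX"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert f["fY"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_halved_sex_coverage_male_like(self):
        ds = self._cov_dataset(30, 15, 15)
        f = mw.sex_features(ds)
        assert f["fX"].iloc[0] == pytest.approx(np.log2(15.01 / 30.01), abs=1e-9)

    def test_absent_y_signal_formula(self):
        # mean chrY coverage 0.3 from integer counts: 3 sites at 1, 7 at 0
        n_each = 10
        chroms = ["chr1"] * n_each + ["chrX"] * n_each + ["chrY"] * n_each
        cov = np.concatenate(
            [
                np.full((n_each, 1), 30.0),
                np.full((n_each, 1), 30.0),
                np.array([1.0] * 3 + [0.0] * 7)[:, None],
            ]
        )
        betas = np.where(cov > 0, 0.5, np.nan)
        ds = _dataset(
            betas, chroms=chroms, positions=list(range(1, n_each + 1)) * 3,
            coverage=cov, platform="rrbs",
        )
        f = mw.sex_features(ds)
        assert f["fY"].iloc[0] == pytest.approx(np.log2(0.31 / 30.01), abs=1e-9)

    def test_global_coverage_rescale_cancels(self):
        ds1 = self._cov_dataset(30, 15, 15)
        ds2 = self._cov_dataset(60, 30, 30)
        f1, f2 = mw.sex_features(ds1), mw.sex_features(ds2)
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=2e-3)

    def test_no_sex_chromosomes_errors(self):
        ds = _dataset(np.full((5, 2), 0.5), coverage=np.full((5, 2), 10.0), platform="rrbs")
        with pytest.raises(DataError, match="sex-chromosome"):
            mw.sex_features(ds)


class TestSexModel:
    def test_separable_cohort_perfect_heldout_accuracy(self):
        feats, labels = mw.simulate_sex_feature_cohort(n_per_class=100, seed=0)
        train = feats.iloc[::2]
        model = mw.train_sex_model(train, labels.iloc[::2], seed=0)
        pred = mw.predict_sex(model, feats.iloc[1::2])
        assert (pred["predicted_sex"] == labels.iloc[1::2]).all()

    def test_boundary_sample_reported_unknown(self):
        model = SexModel(intercept=0.0, weight_fX=1.0, weight_fY=0.0,
                         classes=("female", "male"))
        feats = pd.DataFrame({"fX": [0.0], "fY": [0.0]})  # probability exactly 0.5
        pred = mw.predict_sex(model, feats, confidence=0.8)
        assert pred["predicted_sex"].iloc[0] == "unknown"

    def test_single_class_training_errors(self):
        feats, labels = mw.simulate_sex_feature_cohort(n_per_class=5, seed=1)
        with pytest.raises(DataError, match="two classes"):
            mw.train_sex_model(feats, pd.Series(["male"] * len(feats), index=feats.index))

    def test_serialization_round_trip(self, tmp_path):
        feats, labels = mw.simulate_sex_feature_cohort(n_per_class=20, seed=2)
        model = mw.train_sex_model(feats, labels, seed=0)
        model.to_tsv(tmp_path / "sex.tsv")
        back = SexModel.from_tsv(tmp_path / "sex.tsv")
        p1 = mw.predict_sex(model, feats)
        p2 = mw.predict_sex(back, feats)
        pd.testing.assert_frame_equal(p1, p2)


class TestGeneticNoise:
    def test_ideal_diploid_scores_zero(self):
        ds = _dataset([[0.0], [0.5], [1.0]], snp_probe=[True, True, True])
        assert mw.genetic_noise(ds).iloc[0] == 0.0

    def test_maximal_deviation(self):
        ds = _dataset([[0.25]], snp_probe=[True])
        assert mw.genetic_noise(ds).iloc[0] == pytest.approx(0.25)

    def test_direct_evaluation(self):
        ds = _dataset([[0.1], [0.45], [0.9]], snp_probe=[True, True, True])
        assert mw.genetic_noise(ds).iloc[0] == pytest.approx(np.mean([0.1, 0.05, 0.1]))

    def test_sex_chromosome_probes_excluded(self):
        ds = _dataset(
            [[0.25], [0.0]], chroms=["chrX", "chr1"], positions=[1, 1],
            snp_probe=[True, True],
        )
        assert mw.genetic_noise(ds).iloc[0] == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_under_beta_complement(self, betas):
        b = np.asarray(betas)[:, None]
        ds1 = _dataset(b, snp_probe=[True] * len(betas))
        ds2 = _dataset(1.0 - b, snp_probe=[True] * len(betas))
        assert mw.genetic_noise(ds1).iloc[0] == pytest.approx(
            mw.genetic_noise(ds2).iloc[0], abs=1e-12
        )

    def test_no_flagged_sites_errors(self):
        ds = _dataset([[0.5]])
        with pytest.raises(DataError, match="SNP-probe"):
            mw.genetic_noise(ds)


class TestLump:
    def _ds(self, betas):
        return _dataset(np.asarray(betas, float)[:, None])

    def test_fully_unmethylated_means_pure_immune(self):
        ds = self._ds([0.0, 0.0])
        out = mw.lump_purity(ds, list(ds.site_ids))
        assert out["purity"].iloc[0] == 0.0
        assert out["immune_fraction"].iloc[0] == 1.0

    def test_cap_at_one(self):
        ds = self._ds([0.9, 0.9])
        out = mw.lump_purity(ds, list(ds.site_ids))
        assert out["purity"].iloc[0] == 1.0

    def test_ratio(self):
        ds = self._ds([0.425])
        out = mw.lump_purity(ds, list(ds.site_ids))
        assert out["purity"].iloc[0] == pytest.approx(0.5)
        assert out["n_lump_sites_used"].iloc[0] == 1

    def test_monotone_and_complementary(self):
        rng = np.random.default_rng(0)
        means = np.sort(rng.uniform(0, 1, 15))
        purities = [
            mw.lump_purity(self._ds([m]), ["chr1:1:*"])["purity"].iloc[0] for m in means
        ]
        assert all(b >= a for a, b in zip(purities, purities[1:]))
        out = mw.lump_purity(self._ds([0.3]), ["chr1:1:*"])
        assert out["purity"].iloc[0] + out["immune_fraction"].iloc[0] == 1.0

    def test_absent_sites_error(self):
        ds = self._ds([0.5])
        with pytest.raises(DataError, match="LUMP"):
            mw.lump_purity(ds, ["chr9:9:*"])


class TestDeconvolution:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(0.05, 0.95, (200, 2))
        w_true = np.array([0.3, 0.7])
        b = (R @ w_true)[:, None]
        sites = mw.make_site_table(["chr1"] * 200, range(1, 201), "*")
        ds = mw.MethylationDataset(
            sites=sites,
            samples=pd.DataFrame(index=pd.Index(["s"], name="sample_id")),
            beta=b, platform="synthetic",
        )
        ref = mw.ReferenceProfiles(["a", "b"], pd.DataFrame(R, index=sites.index, columns=["a", "b"]))
        out = mw.deconvolve_celltypes(ds, ref, "sum_eq_one")
        np.testing.assert_allclose(out[["a", "b"]].to_numpy()[0], w_true, atol=1e-6)
        assert out["residual"].iloc[0] < 1e-6

    def test_pure_column_gets_weight_one(self):
        rng = np.random.default_rng(1)
        R = rng.uniform(0.05, 0.95, (150, 3))
        sites = mw.make_site_table(["chr1"] * 150, range(1, 151), "*")
        ds = mw.MethylationDataset(
            sites=sites,
            samples=pd.DataFrame(index=pd.Index(["s"], name="sample_id")),
            beta=R[:, [1]], platform="synthetic",
        )
        ref = mw.ReferenceProfiles(
            ["t0", "t1", "t2"], pd.DataFrame(R, index=sites.index, columns=["t0", "t1", "t2"])
        )
        out = mw.deconvolve_celltypes(ds, ref, "sum_le_one")
        np.testing.assert_allclose(out[["t0", "t1", "t2"]].to_numpy()[0], [0, 1, 0], atol=1e-5)

    def test_noisy_mixture_recovery(self):
        ds, ref, truth = mw.simulate_mixtures(30, 800, 3, noise_sd=0.02, seed=5)
        out = mw.deconvolve_celltypes(ds, ref, "sum_eq_one")
        mae = np.abs(out[ref.cell_types].to_numpy() - truth.to_numpy()).mean()
        assert mae < 0.05

    def test_simplex_point_has_zero_residual(self):
        ds, ref, truth = mw.simulate_mixtures(5, 300, 3, noise_sd=0.0, seed=6)
        out = mw.deconvolve_celltypes(ds, ref, "sum_eq_one")
        assert (out["residual"] < 1e-6).all()

    def test_duplicate_reference_columns_rejected(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(0, 1, 50)
        R = np.column_stack([col, col])
        sites = mw.make_site_table(["chr1"] * 50, range(1, 51), "*")
        ds = mw.MethylationDataset(
            sites=sites,
            samples=pd.DataFrame(index=pd.Index(["s"], name="sample_id")),
            beta=col[:, None], platform="synthetic",
        )
        ref = mw.ReferenceProfiles(["a", "b"], pd.DataFrame(R, index=sites.index, columns=["a", "b"]))
        with pytest.raises(DataError, match="identical"):
            mw.deconvolve_celltypes(ds, ref)
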