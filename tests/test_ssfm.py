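import numpy as np
import pytest

from kneessfm.correspondence import CorrespondentSet
from kneessfm.ssfm import (
    ColumnBlock,
    FeatureMatrix,
    ShapeFieldPCA,
    assemble_features,
    fit_pca,
    modes_to_reach,
    project_subject,
    synthesize_mode,
)
from kneessfm.thickness import SubchondralIndexSet, ThicknessMap


def _toy_inputs():
    """3 subjects, one bone with 2 nodes, 1 thickness value each."""
    arrays = np.array(
        [
            [[0.0, 0, 0], [1, 0, 0]],
            [[0.1, 0, 0], [1.2, 0, 0]],
            [[-0.1, 0, 0], [0.8, 0, 0]],
        ]
    )
    corr = {"femur": CorrespondentSet(["a", "b", "c"], arrays, "femur")}
    maps = {
        "femur": [
            ThicknessMap("a", "femur", np.array([2.0]), np.array([False])),
            ThicknessMap("b", "femur", np.array([2.5]), np.array([False])),
            ThicknessMap("c", "femur", np.array([1.5]), np.array([False])),
        ]
    }
    idx = {"femur": SubchondralIndexSet("femur", np.array([0]))}
    return corr, maps, idx


class TestAssembleFeatures:
    def test_hand_computed_matrix(self):
        corr, maps, idx = _toy_inputs()
        fm = assemble_features(corr, maps, idx)
        # column order: node0 xyz, node1 xyz, thickness
        expected = np.array(
            [
                [0.0, 0, 0, 1.0, 0, 0, 2.0],
                [0.1, 0, 0, 1.2, 0, 0, 2.5],
                [-0.1, 0, 0, 0.8, 0, 0, 1.5],
            ]
        )
        np.testing.assert_allclose(fm.values, expected)
        model = ShapeFieldPCA().fit(fm)
        centred = expected - expected.mean(axis=0)
        live = centred.std(axis=0, ddof=1) > 0
        z = centred[:, live] / centred[:, live].std(axis=0, ddof=1)
        assert np.abs(((fm.values - model.mean_) / model.scale_)[:, live] - z).max() < 1e-12
        np.testing.assert_array_equal(model.zero_sd_mask_, ~live)

    def test_identical_subjects_all_columns_flagged(self):
        corr, maps, idx = _toy_inputs()
        corr["femur"].arrays[:] = corr["femur"].arrays[0]
        for m in maps["femur"]:
            m.thickness[:] = 2.0
        fm = assemble_features(corr, maps, idx)
        model = ShapeFieldPCA().fit(fm)
        assert model.zero_sd_mask_.all()
        z = (fm.values - model.mean_) / model.scale_
        np.testing.assert_allclose(z, 0.0, atol=1e-14)

    def test_reassembly_bit_identical(self):
        corr, maps, idx = _toy_inputs()
        a = assemble_features(corr, maps, idx)
        b = assemble_features(corr, maps, idx)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.blocks == b.blocks

    def test_subject_mismatch_lists_offenders(self):
        corr, maps, idx = _toy_inputs()
        maps["femur"][2] = ThicknessMap("zz", "femur", np.array([1.5]), np.array([False]))
        with pytest.raises(ValueError, match="zz"):
            assemble_features(corr, maps, idx)


class TestFitPCA:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 30))
        model = ShapeFieldPCA().fit(x)
        z = (x - model.mean_) / model.scale_
        evals = np.sort(np.linalg.eigvalsh(np.cov(z, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_, evals[: model.n_components_], atol=1e-8
        )

    def test_rank_one_matrix_single_mode(self):
        u = np.array([1.0, 2, 3, 4.0])
        v = np.array([0.5, -1, 2.0])
        model = ShapeFieldPCA(scaling="per-column").fit(np.outer(u, v))
        assert model.explained_variance_[0] > 1e-10
        assert np.all(model.explained_variance_[1:] < 1e-20)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 20))
        model = ShapeFieldPCA().fit(x)
        z = (x - model.mean_) / model.scale_
        assert abs(model.explained_variance_.sum() - np.var(z, axis=0, ddof=1).sum()) < 1e-8

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 15)) * rng.uniform(0.5, 5, size=15)
        model = ShapeFieldPCA().fit(x)
        back = model.inverse_transform(model.scores_)
        assert np.abs(back - x).max() < 1e-8

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(3)
        model = ShapeFieldPCA().fit(rng.normal(size=(20, 40)))
        cov = np.cov(model.scores_, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * model.explained_variance_[0]

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 12))
        a = ShapeFieldPCA().fit(x)
        b = ShapeFieldPCA().fit(x.copy())
        np.testing.assert_array_equal(a.components_, b.components_)
        k = np.argmax(np.abs(a.components_), axis=1)
        assert np.all(a.components_[np.arange(len(k)), k] > 0)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            ShapeFieldPCA().fit(np.zeros((2, 5)))


class TestModesToReach:
    def test_hand_case(self):
        model = ShapeFieldPCA()
        model.explained_variance_ratio_ = np.array([0.60, 0.25, 0.10, 0.05])
        model.explained_variance_ = model.explained_variance_ratio_.copy()
        model.components_ = np.eye(4)
        model.n_components_ = 4
        assert model.modes_to_reach(0.90) == 3
        assert model.modes_to_reach(0.999999) == 4
        with pytest.raises(ValueError):
            model.modes_to_reach(1.5)


class TestSynthesizeAndProject:
    def _model(self):
        corr, maps, idx = _toy_inputs()
        return assemble_features(corr, maps, idx)

    def test_zero_multiple_gives_mean(self):
        fm = self._model()
        model = fit_pca(fm)
        row = model.synthesize_mode(1, 0.0)
        np.testing.assert_allclose(row, fm.values.mean(axis=0), atol=1e-12)
        clouds, fields = synthesize_mode(model, 1, 0.0)
        assert clouds["femur"].points.shape == (2, 3)
        assert fields["femur"].shape == (1,)

    def test_plus_minus_symmetry(self):
        model = fit_pca(self._model())
        plus = model.synthesize_mode(1, 1.0)
        minus = model.synthesize_mode(1, -1.0)
        np.testing.assert_allclose(
            (plus + minus) / 2, model.mean_, atol=1e-9
        )

    def test_size_mode_monotonic_in_multiple(self):
        """A pure size cohort: synthesized extent and thickness grow with c."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=(1, 9))
        factors = np.array([0.9, 0.95, 1.0, 1.05, 1.1])[:, None]
        coords = factors * np.abs(base)
        thick = factors * 2.0
        corr = {
            "femur": CorrespondentSet(
                [f"s{i}" for i in range(5)], coords.reshape(5, 3, 3), "femur"
            )
        }
        maps = {
            "femur": [
                ThicknessMap(f"s{i}", "femur", np.array([thick[i, 0]]), np.array([False]))
                for i in range(5)
            ]
        }
        model = fit_pca(assemble_features(corr, maps))
        extents, means = [], []
        for c in (-2.0, 0.0, 2.0):
            clouds, fields = synthesize_mode(model, 1, c)
            extents.append(np.linalg.norm(clouds["femur"].points))
            means.append(fields["femur"].mean())
        assert (np.diff(extents) > 0).all() or (np.diff(extents) < 0).all()
        assert (np.diff(means) > 0).all() or (np.diff(means) < 0).all()
        # larger bone <-> thicker cartilage: both move together
        assert np.sign(np.diff(extents)[0]) == np.sign(np.diff(means)[0])

    def test_projection_roundtrip(self):
        fm = self._model()
        model = fit_pca(fm)
        for i in range(3):
            np.testing.assert_allclose(
                project_subject(model, fm.values[i]), model.scores_[i], atol=1e-9
            )
        np.testing.assert_allclose(
            project_subject(model, fm.values.mean(axis=0)), 0.0, atol=1e-9
        )

    def test_projection_of_synthesized_offset(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 8))
        model = ShapeFieldPCA().fit(x)
        sd3 = np.sqrt(model.explained_variance_[2])
        row = model.mean_ + 2.0 * sd3 * model.components_[2] * model.scale_
        scores = model.transform(row)[0]
        expected = np.zeros(model.n_components_)
        expected[2] = 2.0 * sd3
        np.testing.assert_allclose(scores, expected, atol=1e-9)

    def test_layout_mismatch_raises(self):
        model = fit_pca(self._model())
        with pytest.raises(ValueError, match="layout"):
            model.transform(np.zeros(3))


class TestScalingVariants:
    def test_per_block_differs_from_per_column(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(8, 6)) * [1, 2, 4, 8, 16, 32]
        thick = rng.normal(size=(8, 2)) * 0.1
        fm = FeatureMatrix(
            np.hstack([coords, thick]),
            [f"s{i}" for i in range(8)],
            [ColumnBlock("femur", "coords", 6), ColumnBlock("femur", "thickness", 2)],
        )
        a = ShapeFieldPCA(scaling="per-column").fit(fm)
        b = ShapeFieldPCA(scaling="per-block").fit(fm)
        assert not np.allclose(a.explained_variance_ratio_, b.explained_variance_ratio_)
        # per-block: every column in a block shares one divisor
        assert np.unique(np.round(b.scale_[:6], 12)).size == 1
        assert np.unique(np.round(b.scale_[6:], 12)).size == 1

    def test_invalid_scaling_rejected(self):
        with pytest.raises(ValueError, match="scaling"):
            ShapeFieldPCA(scaling="whatever").fit(np.zeros((4, 3)))


class TestPersistence:
    def test_hdf5_roundtrip(self, tmp_path):
        corr, maps, idx = _toy_inputs()
        model = fit_pca(assemble_features(corr, maps, idx))
        path = tmp_path / "model.h5"
        model.save(path)
        back = ShapeFieldPCA.load(path)
        np.testing.assert_array_equal(back.components_, model.components_)
        np.testing.assert_array_equal(back.mean_, model.mean_)
        np.testing.assert_array_equal(back.scores_, model.scores_)
        assert back.blocks_ == model.blocks_
        assert back.scaling == model.scaling
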