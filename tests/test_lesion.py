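import numpy as np
import pytest

import popfactor as pf
from popfactor.errors import RankError
from popfactor.lesion import _permuted_design

from conftest import random_orthogonal


class TestFitClassStructure:
    def test_two_class_hand_example(self, grouped_two_class):
        """Centers (±1,0), residuals along e2: one paired PC, W e1 = e2."""
        responses, _, labels = grouped_two_class
        st = pf.fit_class_structure(responses, labels)
        assert st.n_paired == 1
        np.testing.assert_allclose(np.abs(st.inter_pcs[:, 0]), [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(st.intra_pcs[:, 0]), [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(
            np.abs(st.rotation @ np.array([1.0, 0.0])), [0.0, 1.0], atol=1e-12
        )

    def test_isometry_on_inter_span(self, class_dataset):
        responses, _, labels = class_dataset
        st = pf.fit_class_structure(responses, labels)
        assert np.allclose(st.inter_pcs.T @ st.inter_pcs, np.eye(st.n_paired), atol=1e-8)
        assert np.allclose(st.intra_pcs.T @ st.intra_pcs, np.eye(st.n_paired), atol=1e-8)
        vecs = st.inter_pcs @ np.random.default_rng(0).normal(size=(st.n_paired, 5))
        np.testing.assert_allclose(
            np.linalg.norm(st.rotation @ vecs, axis=0),
            np.linalg.norm(vecs, axis=0),
            atol=1e-8,
        )

    def test_singleton_class_rejected(self):
        rm = pf.ResponseMatrix(np.eye(3), ["a", "b", "c"])
        with pytest.raises(RankError):
            pf.fit_class_structure(rm, ["x", "x", "y"])

    def test_intra_rank_deficit_rejected(self):
        # 3 classes (inter rank 2) but residuals confined to one axis
        centers = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        rows, labels = [], []
        for c, center in enumerate(centers):
            rows += [center + [0, 0, 0.5], center - [0, 0, 0.5]]
            labels += [f"c{c}"] * 2
        rm = pf.ResponseMatrix(np.array(rows), [f"r{i}" for i in range(6)])
        with pytest.raises(RankError):
            pf.fit_class_structure(rm, labels)


class TestRotationLesion:
    def test_two_class_centers_rotate(self, grouped_two_class):
        """Worked 2-D example: centers move from (±1,0) to (0,±1)."""
        responses, _, labels = grouped_two_class
        lesioned = pf.rotation_lesion(responses, labels)
        st = pf.fit_class_structure(lesioned, labels)
        np.testing.assert_allclose(
            np.abs(st.class_centers), [[0.0, 1.0], [0.0, 1.0]], atol=1e-12
        )
        # residuals carried over bitwise
        orig = pf.fit_class_structure(responses, labels)
        np.testing.assert_array_equal(
            lesioned.values - np.repeat(st.class_centers, 2, axis=0),
            responses.values - np.repeat(orig.class_centers, 2, axis=0),
        )

    def test_identity_when_inter_equals_intra(self):
        """If inter and intra PCs coincide, the lesion is a no-op."""
        rng = np.random.default_rng(3)
        centers = np.zeros((3, 4))
        centers[:, 0] = [-2.0, 0.0, 2.0]
        rows, labels = [], []
        for c, center in enumerate(centers):
            for i in range(20):
                rows.append(center + [rng.normal(), 0.0, 0.0, 0.0])
                labels.append(f"c{c}")
        rm = pf.ResponseMatrix(np.array(rows), [f"r{i}" for i in range(60)])
        lesioned = pf.rotation_lesion(rm, labels)
        np.testing.assert_allclose(lesioned.values, rm.values, atol=1e-8)

    def test_conservation_laws(self, class_dataset):
        responses, _, labels = class_dataset
        lesioned = pf.rotation_lesion(responses, labels)
        before = pf.fit_class_structure(responses, labels)
        after = pf.fit_class_structure(lesioned, labels)

        # within-class deviations bitwise conserved
        def deviations(rm, st):
            centers = dict(zip(st.class_order, st.class_centers))
            return rm.values - np.stack(
                [centers[l] for l in st.class_labels.loc[rm.condition_ids]]
            )

        np.testing.assert_allclose(
            deviations(lesioned, after), deviations(responses, before), atol=1e-8
        )
        # within-class covariance conserved
        dev_b, dev_a = deviations(responses, before), deviations(lesioned, after)
        np.testing.assert_allclose(
            dev_a.T @ dev_a / len(dev_a), dev_b.T @ dev_b / len(dev_b), atol=1e-8
        )
        # inter-center variance spectrum conserved
        spec = lambda st: np.sort(
            np.linalg.svd(st.class_centers - st.global_center, compute_uv=False)
        )
        np.testing.assert_allclose(spec(after), spec(before), atol=1e-8)
        # pairwise center distances conserved
        dist = lambda st: np.linalg.norm(
            st.class_centers[:, None] - st.class_centers[None], axis=2
        )
        np.testing.assert_allclose(dist(after), dist(before), atol=1e-8)

    def test_invariance_conserved_factorization_destroyed(self, class_dataset):
        responses, design, labels = class_dataset
        lesioned = pf.rotation_lesion(responses, labels)
        inv_b = pf.invariance(responses, design, "non_class")
        inv_a = pf.invariance(lesioned, design, "non_class")
        assert inv_a == pytest.approx(inv_b, abs=1e-8)
        for fn in (pf.factorization_pca, pf.factorization_cov):
            assert fn(lesioned, design, "class") < fn(responses, design, "class")

    def test_decoding_drops(self, class_dataset):
        responses, _, labels = class_dataset
        lesioned = pf.rotation_lesion(responses, labels)
        acc_b = pf.cv_decode(responses, labels, folds=4, regularization_grid=[1.0]).accuracy
        acc_a = pf.cv_decode(lesioned, labels, folds=4, regularization_grid=[1.0]).accuracy
        assert acc_a < acc_b


class TestShuffleNull:
    def test_extreme_rank_percentile(self, class_dataset):
        """Strong planted structure beats the whole null: percentile 100."""
        responses, design, _ = class_dataset
        null = pf.shuffle_null(
            responses, design, "class", "factorization_cov", n_permutations=99, seed=0
        )
        assert null.percentile == 100.0
        assert null.observed > null.null_samples.max()

    def test_seed_reproducible(self, class_dataset):
        responses, design, _ = class_dataset
        a = pf.shuffle_null(responses, design, "class", "factorization_cov", 25, seed=5)
        b = pf.shuffle_null(responses, design, "class", "factorization_cov", 25, seed=5)
        np.testing.assert_array_equal(a.null_samples, b.null_samples)
        assert a.percentile == b.percentile

    def test_percentile_rotation_invariant(self, class_dataset):
        responses, design, _ = class_dataset
        q = random_orthogonal(responses.n_features, seed=9)
        rotated = responses.with_values(responses.values @ q)
        a = pf.shuffle_null(responses, design, "class", "factorization_pca", 30, seed=2)
        b = pf.shuffle_null(rotated, design, "class", "factorization_pca", 30, seed=2)
        assert a.percentile == pytest.approx(b.percentile)

    def test_low_permutation_warning(self, class_dataset, caplog):
        responses, design, _ = class_dataset
        import logging

        with caplog.at_level(logging.WARNING, logger="popfactor.lesion"):
            pf.shuffle_null(
                responses, design, "class", "factorization_cov", n_permutations=10
            )
        assert any("unstable" in rec.message for rec in caplog.records)

    def test_augmentation_mode_permutes_scene_assignment(self):
        ds = pf.gen_augmentation_responses(
            pf.AugmentationSimConfig(n_units=15, n_base_scenes=8, n_levels=4, seed=0)
        )
        rng = np.random.default_rng(0)
        permuted = _permuted_design(ds.design, rng)
        assert permuted.mode == "augmentation"
        # level-count bookkeeping stays valid, scene assignment moved
        assert not permuted.table["base_scene_id"].equals(ds.design.table["base_scene_id"])
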