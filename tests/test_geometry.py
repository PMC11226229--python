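import numpy as np
import pytest

import popfactor as pf
from popfactor.errors import (
    DegenerateSubspaceError,
    DesignError,
    UndefinedScoreError,
)
from popfactor.geometry import pca_subspace, total_variance

from conftest import make_design, random_orthogonal


def two_scene_design():
    meta = [
        ("s0l0", "s0", "object_pose", 0, None),
        ("s0l1", "s0", "object_pose", 1, None),
        ("s1l0", "s1", "object_pose", 0, None),
        ("s1l1", "s1", "object_pose", 1, None),
    ]
    return make_design(meta)


class TestParamVariance:
    def test_hand_computed_two_level_case(self):
        """Two responses (0,0) and (2,0): deviations ±1, n-denominator variance 1."""
        values = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 1.0], [5.0, 1.0]])
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        design = two_scene_design()
        # scene s0 contributes 1.0, scene s1 contributes 0.0 -> mean 0.5
        assert pf.param_variance(rm, design, "object_pose") == pytest.approx(0.5)

    def test_identical_levels_give_zero(self):
        values = np.tile(np.array([[1.0, 2.0]]), (4, 1))
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        assert pf.param_variance(rm, two_scene_design(), "object_pose") == 0.0

    def test_absent_param_raises(self):
        rm = pf.ResponseMatrix(np.eye(4), ["s0l0", "s0l1", "s1l0", "s1l1"])
        with pytest.raises(KeyError):
            pf.param_variance(rm, two_scene_design(), "lighting")

    def test_generator_variance_recovery(self):
        """Estimated parameter variance tracks the planted latent variance."""
        cfg = pf.AugmentationSimConfig(
            n_units=40,
            params=(pf.ParamSpec("background", 2, 2.0), pf.ParamSpec("lighting", 2, 0.5)),
            noise_sd=0.0,
            seed=4,
        )
        ds = pf.gen_augmentation_responses(cfg)
        est = pf.param_variance(ds.responses, ds.design, "background")
        # per-scene sample variance with n denominator is biased by (1 - 1/levels)
        expected = 2.0 * (1 - 1 / cfg.n_levels)
        assert est == pytest.approx(expected, rel=0.1)


class TestSubspaces:
    def test_cumulative_threshold_rule(self):
        """Exact spectrum (9, 1): threshold 0.9 ties at one component."""
        pts = np.array([[3.0, 0.0], [-3.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        # covariance eigenvalues are exactly (4.5, 0.5): cumulative (0.9, 1.0)
        assert pca_subspace(pts, 0.9).rank == 1  # tie resolves to smaller k
        assert pca_subspace(pts, 0.91).rank == 2
        assert pca_subspace(pts, 1.0).rank == 2

    def test_rank_one_averages(self):
        values = np.array(
            [[1.0, 0.0], [1.0, 0.0], [3.0, 0.0], [3.0, 0.0]]
        )
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        sub = pf.other_param_subspace(rm, two_scene_design(), "object_pose", 0.9)
        assert sub.rank == 1
        assert abs(sub.basis[0, 0]) == pytest.approx(1.0)

    def test_degenerate_subspace_raises(self):
        values = np.tile(np.array([[1.0, 2.0]]), (4, 1))
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        with pytest.raises(DegenerateSubspaceError):
            pf.other_param_subspace(rm, two_scene_design(), "object_pose")


class TestFactorization:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 45.0, 60.0, 90.0])
    @pytest.mark.parametrize("variant", ["pca", "cov"])
    def test_closed_form_oracle(self, theta, variant):
        """Noiseless single-direction parameters: score = 1 - cos^2(theta)."""
        ds = pf.gen_two_param_oracle(theta, n_units=10, n_scenes=50, seed=1)
        if variant == "pca":
            got = pf.factorization_pca(ds.responses, ds.design, "object_pose", 0.9)
        else:
            got = pf.factorization_cov(ds.responses, ds.design, "object_pose")
        expected = 1.0 - np.cos(np.deg2rad(theta)) ** 2
        assert got == pytest.approx(expected, abs=1e-6)

    def test_hand_projection_half(self):
        """Other subspace e1, deviations along (e1+e2)/sqrt(2): factorization 0.5."""
        ds = pf.gen_two_param_oracle(45.0, n_units=3, n_scenes=20, seed=2)
        got = pf.factorization_pca(ds.responses, ds.design, "object_pose")
        assert got == pytest.approx(0.5, abs=1e-9)

    def test_cov_identical_and_orthogonal_limits(self):
        ds0 = pf.gen_two_param_oracle(0.0, seed=3)
        ds90 = pf.gen_two_param_oracle(90.0, seed=3)
        assert pf.factorization_cov(ds0.responses, ds0.design, "object_pose") == (
            pytest.approx(0.0, abs=1e-9)
        )
        assert pf.factorization_cov(ds90.responses, ds90.design, "object_pose") == (
            pytest.approx(1.0, abs=1e-9)
        )

    def test_zero_param_variance_raises(self):
        values = np.array(
            [[1.0, 0.0], [1.0, 0.0], [3.0, 1.0], [3.0, -1.0]]
        )
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        meta = [
            ("s0l0", "s0", "object_pose", 0, None),
            ("s0l1", "s0", "object_pose", 1, None),
            ("s1l0", "s0", "background", 0, None),
            ("s1l1", "s0", "background", 1, None),
        ]
        design = make_design(meta)
        with pytest.raises(UndefinedScoreError):
            pf.factorization_pca(rm, design, "object_pose")

    def test_single_param_cov_needs_other(self):
        rm = pf.ResponseMatrix(np.eye(4), ["s0l0", "s0l1", "s1l0", "s1l1"])
        with pytest.raises(DesignError):
            pf.factorization_cov(rm, two_scene_design(), "object_pose")

    def test_scores_bounded(self):
        """Both variants stay in [0, 1] on noisy generated data."""
        cfg = pf.AugmentationSimConfig(
            n_units=30,
            n_base_scenes=20,
            n_levels=5,
            params=tuple(
                pf.ParamSpec(n, 2, 1.0, 0.6) for n in pf.PARAM_VOCABULARY
            ),
            noise_sd=0.5,
            seed=5,
        )
        ds = pf.gen_augmentation_responses(cfg)
        for p in pf.PARAM_VOCABULARY:
            for fn in (pf.factorization_pca, pf.factorization_cov):
                score = fn(ds.responses, ds.design, p)
                assert 0.0 <= score <= 1.0

    def test_rotation_equivariance(self):
        """Orthogonal feature transforms leave every score unchanged."""
        cfg = pf.AugmentationSimConfig(
            n_units=20,
            n_base_scenes=15,
            n_levels=4,
            params=(
                pf.ParamSpec("background", 2, 1.0, 0.4),
                pf.ParamSpec("object_pose", 3, 2.0, 0.4),
            ),
            noise_sd=0.2,
            seed=6,
        )
        ds = pf.gen_augmentation_responses(cfg)
        q = random_orthogonal(20, seed=7)
        rotated = ds.responses.with_values(ds.responses.values @ q)
        for p in ("background", "object_pose"):
            assert pf.factorization_pca(
                rotated, ds.design, p
            ) == pytest.approx(pf.factorization_pca(ds.responses, ds.design, p), abs=1e-8)
            assert pf.factorization_cov(
                rotated, ds.design, p
            ) == pytest.approx(pf.factorization_cov(ds.responses, ds.design, p), abs=1e-8)
            assert pf.invariance(rotated, ds.design, p) == pytest.approx(
                pf.invariance(ds.responses, ds.design, p), abs=1e-8
            )

    def test_level_labels_exchangeable(self):
        """Permuting level labels within a base scene changes nothing."""
        cfg = pf.AugmentationSimConfig(
            n_units=15, n_base_scenes=10, n_levels=5, noise_sd=0.1, seed=8
        )
        ds = pf.gen_augmentation_responses(cfg)
        rng = np.random.default_rng(0)
        table = ds.design.table.copy()
        for (_, _), idx in table.groupby(["base_scene_id", "varied_param"]).groups.items():
            table.loc[idx, "level"] = rng.permutation(table.loc[idx, "level"].to_numpy())
        shuffled = pf.AugmentationDesign(table)
        for p in ("background", "lighting"):
            assert pf.factorization_pca(ds.responses, shuffled, p) == pytest.approx(
                pf.factorization_pca(ds.responses, ds.design, p)
            )


class TestInvariance:
    def test_direct_arithmetic(self):
        """var_param = 2, var_all = 8 gives invariance 0.75 (checked end to end)."""
        # scene deviations ±sqrt(2) along e1 -> var_param = 2;
        # plus scene centers chosen so total variance is 8
        a = np.sqrt(2.0)
        values = np.array([[-3.0 - a, 0.0], [-3.0 + a, 0.0], [3.0 - a, 0.0], [3.0 + a, 0.0]])
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        design = two_scene_design()
        v_param = pf.param_variance(rm, design, "object_pose")
        v_all = total_variance(values)
        assert v_param == pytest.approx(2.0)
        assert v_all == pytest.approx(11.0)
        assert pf.invariance(rm, design, "object_pose") == pytest.approx(1 - 2 / 11)

    def test_zero_param_variance_fully_invariant(self):
        values = np.array([[1.0, 0.0], [1.0, 0.0], [3.0, 0.0], [3.0, 0.0]])
        rm = pf.ResponseMatrix(values, ["s0l0", "s0l1", "s1l0", "s1l1"])
        assert pf.invariance(rm, two_scene_design(), "object_pose") == pytest.approx(1.0)

    def test_within_subspace_consistency_and_ordering(self, class_dataset):
        responses, design, _ = class_dataset
        raw = pf.invariance(responses, design, "non_class")
        within = pf.invariance_within_subspace(
            responses, design, "non_class", "class", threshold=0.9
        )
        # orthogonal construction: the class subspace sheds nuisance variance
        assert within >= raw
        # full-rank target subspace reduces to plain invariance
        full = pf.invariance_within_subspace(
            responses, design, "non_class", "class", threshold=1.0
        )
        assert full >= raw


class TestDimensionality:
    def test_participation_ratio_formula(self):
        rng = np.random.default_rng(0)
        # exact spectrum via construction: points = rows of diag(sqrt(lam)) @ basis
        n = 4000
        z = rng.normal(size=(n, 2))
        z = (z - z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(z.T, bias=True)).T)
        pts = z * np.sqrt([4.0, 1.0])
        rm = pf.ResponseMatrix(pts, [f"c{i}" for i in range(n)])
        assert pf.dimensionality(rm, "participation_ratio") == pytest.approx(
            25 / 17, abs=1e-6
        )

    def test_isotropic_cloud(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(5000, 5))
        z = (z - z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(z.T, bias=True)).T)
        rm = pf.ResponseMatrix(z, [f"c{i}" for i in range(5000)])
        assert pf.dimensionality(rm, "participation_ratio") == pytest.approx(5.0, abs=1e-6)

    def test_pc_count_rule(self):
        values = np.vstack([np.eye(2) * [3.0, 1.0], -np.eye(2) * [3.0, 1.0]])
        rm = pf.ResponseMatrix(values, list("abcd"))
        assert pf.dimensionality(rm, "pc_count", threshold=0.9) == 1
        assert pf.dimensionality(rm, "pc_count", threshold=0.95) == 2


class TestMovie:
    def test_orthogonal_local_subspace(self):
        mv = pf.gen_movie_responses(400, local_alignment=0.0, seed=0)
        fact, inv = pf.movie_factorization(mv, "pca")
        assert fact == pytest.approx(1.0, abs=1e-8)
        fact_c, _ = pf.movie_factorization(mv, "cov")
        assert fact_c == pytest.approx(1.0, abs=1e-8)

    def test_cov_oracle_at_half_alignment(self):
        mv = pf.gen_movie_responses(
            4000, local_dim=1, global_dim=1, local_alignment=0.5, seed=1
        )
        fact, _ = pf.movie_factorization(mv, "cov")
        assert fact == pytest.approx(0.75, abs=1e-9)

    def test_fully_aligned_local_variance(self):
        mv = pf.gen_movie_responses(
            2000, local_dim=1, global_dim=1, local_alignment=1.0, seed=2
        )
        fact, _ = pf.movie_factorization(mv, "cov")
        assert fact == pytest.approx(0.0, abs=1e-9)

    def test_zero_local_variance(self):
        mv = pf.gen_movie_responses(100, local_var=0.0, seed=3)
        with pytest.raises(UndefinedScoreError) as exc:
            pf.movie_factorization(mv, "pca")
        assert exc.value.invariance == 1.0

    def test_odd_frame_count_rejected(self):
        rm = pf.ResponseMatrix(np.random.default_rng(0).normal(size=(5, 3)), list("abcde"))
        with pytest.raises(DesignError):
            pf.movie_factorization(rm)


def test_geometry_scores_report(class_dataset):
    responses, design, _ = class_dataset
    scores = pf.geometry_scores(responses, design)
    assert set(scores.factorization_pca) == {"class", "non_class"}
    assert scores.participation_ratio >= 1.0
    assert scores.pc_count >= 1
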