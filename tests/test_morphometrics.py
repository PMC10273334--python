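"""Procrustes superimposition, sliding, shape PCA, and morphospace summaries."""

import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes

from paleoneuro import (
    LabyrinthShapeParams,
    LandmarkConfiguration,
    ValidationError,
    generate_labyrinth,
    generate_population,
    gpa,
    morphospace_summary,
    pca_shapes,
    procrustes_ss,
    slide_semilandmarks,
)
from paleoneuro.morphometrics import _center_and_scale, _optimal_rotation

from conftest import apply_rigid_motion


def _noisy_population(n=20, noise=0.02, seed=11, **shape_kwargs):
    params = LabyrinthShapeParams(noise_sd=noise, **shape_kwargs)
    return generate_population([(params, "g", n)], seed=seed)[0]


class TestGPA:
    def test_single_configuration_is_its_own_consensus(self):
        config = generate_labyrinth(LabyrinthShapeParams())
        aligned = gpa([config])
        assert aligned.n == 1 and aligned.iterations == 1 and aligned.converged
        centered, _ = _center_and_scale(config.coordinates)
        # consensus equals the centred unit-size copy, up to orientation
        rot = _optimal_rotation(centered, aligned.consensus)
        np.testing.assert_allclose(centered @ rot, aligned.consensus, atol=1e-12)

    def test_unit_size_zero_centroid_and_consensus_mean(self):
        aligned = gpa(_noisy_population())
        centroids = aligned.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        sizes = np.sqrt((aligned.aligned**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            aligned.consensus, aligned.aligned.mean(axis=0), atol=1e-9
        )

    def test_rigid_copies_align_exactly(self):
        """Two copies of one shape differing by a rigid motion plus scale
        superimpose to identical coordinates (Procrustes distance 0)."""
        rng = np.random.default_rng(5)
        base = generate_labyrinth(LabyrinthShapeParams())
        moved = apply_rigid_motion(base, rng)
        moved.specimen_id = "copy"
        aligned = gpa([base, moved])
        np.testing.assert_allclose(
            aligned.aligned[0], aligned.aligned[1], atol=1e-8
        )
        assert procrustes_ss(aligned) < 1e-15

    def test_pairwise_agreement_with_scipy_procrustes(self):
        """For two configurations, the residual disparity of our GPA matches
        scipy's pairwise orthogonal Procrustes solution. scipy additionally
        lets the second shape rescale, so agreement is asymptotic in the
        shape distance: tight at small noise."""
        configs = _noisy_population(n=2, noise=0.005, seed=3)
        aligned = gpa(configs)
        _, _, disparity = scipy_procrustes(
            configs[0].coordinates, configs[1].coordinates
        )
        d_ours = ((aligned.aligned[0] - aligned.aligned[1]) ** 2).sum()
        assert d_ours == pytest.approx(disparity, rel=0.02)

    def test_consensus_recovers_generating_mean_shape(self):
        """With n=20 specimens at landmark noise sigma, the consensus sits
        within 3*sigma/sqrt(20) of the generating mean shape in RMS
        per-landmark deviation (and within 3*sigma*sqrt(3)/sqrt(20) at every
        single landmark)."""
        sigma, n = 0.02, 20
        configs = _noisy_population(n=n, noise=sigma, seed=11)
        aligned = gpa(configs)
        truth, _ = _center_and_scale(
            generate_labyrinth(LabyrinthShapeParams()).coordinates
        )
        truth = truth @ _optimal_rotation(truth, aligned.consensus)
        per_landmark = np.linalg.norm(aligned.consensus - truth, axis=1)
        assert np.sqrt((per_landmark**2).mean()) < 3 * sigma / np.sqrt(n)
        assert per_landmark.max() < 3 * sigma * np.sqrt(3) / np.sqrt(n)

    def test_degenerate_configuration_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValidationError, match="degenerate"):
            gpa([LandmarkConfiguration("line", line, ["C"] * 5)])

    def test_non_homologous_configs_rejected(self):
        a = generate_labyrinth(LabyrinthShapeParams())
        counts = dict(LabyrinthShapeParams().canal_landmark_counts)
        counts["ASC"] += 2
        b = generate_labyrinth(
            LabyrinthShapeParams(canal_landmark_counts=counts), "b"
        )
        with pytest.raises(ValidationError, match="homologous"):
            gpa([a, b])


class TestSliding:
    def test_off_mode_is_identity(self):
        aligned = gpa(_noisy_population(n=5))
        assert slide_semilandmarks(aligned, mode="off") is aligned

    def test_identical_shapes_are_a_fixed_point(self):
        """When all specimens already coincide with the consensus, sliding
        displaces nothing."""
        base = generate_labyrinth(LabyrinthShapeParams())
        configs = [
            LandmarkConfiguration(f"s{i}", base.coordinates.copy(), base.curve_ids)
            for i in range(4)
        ]
        aligned = gpa(configs)
        slid = slide_semilandmarks(aligned)
        np.testing.assert_allclose(slid.aligned, aligned.aligned, atol=1e-9)

    def test_sliding_never_increases_procrustes_ss(self):
        for seed in (1, 2, 3):
            aligned = gpa(_noisy_population(n=12, noise=0.03, seed=seed))
            before = procrustes_ss(aligned)
            after = procrustes_ss(slide_semilandmarks(aligned))
            assert after <= before + 1e-12

    def test_curve_with_too_few_landmarks_rejected(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3))
        configs = [
            LandmarkConfiguration(f"s{i}", coords + rng.normal(size=(5, 3)) * 0.01,
                                  ["A", "A", "A", "B", "B"])
            for i in range(3)
        ]
        aligned = gpa(configs)
        with pytest.raises(ValidationError, match="fewer than 3"):
            slide_semilandmarks(aligned)


class TestShapePCA:
    def test_agrees_with_explicit_covariance_eigendecomposition(self):
        """On small instances the SVD-based PCA matches a brute-force
        eigen-decomposition of the explicitly formed covariance matrix."""
        rng = np.random.default_rng(9)
        for n, k in [(5, 4), (8, 6), (10, 10)]:
            base = rng.normal(size=(k, 3))
            configs = [
                LandmarkConfiguration(
                    f"s{i}", base + rng.normal(size=(k, 3)) * 0.05, ["C"] * k
                )
                for i in range(n)
            ]
            aligned = gpa(configs)
            result = pca_shapes(aligned)
            flat = aligned.aligned.reshape(n, 3 * k) - aligned.consensus.ravel()
            cov = flat.T @ flat / (n - 1)
            oracle = np.sort(np.linalg.eigvalsh(cov))[::-1][: len(result.eigenvalues)]
            np.testing.assert_allclose(
                result.eigenvalues, oracle, atol=1e-8
            )

    def test_variance_fractions_normalised_and_sorted(self):
        result = pca_shapes(gpa(_noisy_population(n=15)))
        assert result.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(result.eigenvalues) <= 1e-15)
        assert np.all(result.eigenvalues >= -1e-15)

    def test_rank_bound(self):
        """At most min(n-1, 3k-7) non-zero eigenvalues survive the removal of
        translation, scale, and rotation."""
        configs = _noisy_population(n=6)
        result = pca_shapes(gpa(configs))
        k = configs[0].k
        nonzero = (result.eigenvalues > 1e-12 * result.eigenvalues[0]).sum()
        assert nonzero <= min(len(configs) - 1, 3 * k - 7)

    def test_identical_shapes_give_zero_variance(self):
        base = generate_labyrinth(LabyrinthShapeParams())
        configs = [
            LandmarkConfiguration(f"s{i}", base.coordinates.copy(), base.curve_ids)
            for i in range(5)
        ]
        result = pca_shapes(gpa(configs))
        assert np.abs(result.eigenvalues).max() < 1e-12
        assert np.abs(result.scores).max() < 1e-9

    def test_two_cluster_separation_on_pc1(self, two_cluster_population):
        """Groups generated with a height/width effect >= 5x the landmark
        noise occupy disjoint PC1 score intervals."""
        configs, _ = two_cluster_population
        result = pca_shapes(gpa(configs))
        pc1 = result.scores[:, 0]
        g1, g2 = pc1[:10], pc1[10:]
        assert g1.max() < g2.min() or g2.max() < g1.min()

    def test_fewer_than_three_specimens_rejected(self):
        with pytest.raises(ValidationError, match="3 specimens"):
            pca_shapes(gpa(_noisy_population(n=2)))

    def test_end_to_end_rigid_motion_invariance(self, two_cluster_population):
        """Random rotations/translations/scales applied independently to all
        input configurations change no PCA score by more than 1e-6."""
        configs, _ = two_cluster_population
        rng = np.random.default_rng(17)
        moved = [apply_rigid_motion(c, rng) for c in configs]
        s0 = pca_shapes(gpa(configs)).scores
        s1 = pca_shapes(gpa(moved)).scores
        assert np.abs(s0 - s1).max() < 1e-6


class TestMorphospaceSummary:
    def test_disjoint_groups_have_zero_overlap(self, two_cluster_population):
        configs, records = two_cluster_population
        result = pca_shapes(gpa(configs))
        summary = morphospace_summary(result, records, grouping="skull_class")
        pc1 = summary.overlap[summary.overlap["component"] == "PC1"]
        assert (pc1["overlap_fraction"] == 0.0).all()
        assert len(summary.pairwise_distances) == 1
        assert summary.pairwise_distances["distance"].iloc[0] > 0

    def test_single_group_gives_empty_pairwise_table(self):
        configs, records = generate_population(
            [(LabyrinthShapeParams(noise_sd=0.01), "longirostrine", 5)], seed=2
        )
        summary = morphospace_summary(
            pca_shapes(gpa(configs)), records, grouping="skull_class"
        )
        assert summary.pairwise_distances.empty
        assert summary.overlap.empty
        assert list(summary.centroids.index) == ["longirostrine"]

    def test_known_three_group_centroid_ordering(self):
        """Three groups spaced along the height/width axis produce PC1
        centroids in the generating order."""
        groups = [
            (LabyrinthShapeParams(height_width_ratio=h, noise_sd=0.01), label, 6)
            for h, label in [(0.7, "longirostrine"), (1.0, "mesorostrine"),
                             (1.3, "brevirostrine")]
        ]
        configs, records = generate_population(groups, seed=8)
        result = pca_shapes(gpa(configs))
        summary = morphospace_summary(result, records, grouping="skull_class")
        c = summary.centroids["PC1"]
        ordering = c.loc[["longirostrine", "mesorostrine", "brevirostrine"]]
        assert ordering.is_monotonic_increasing or ordering.is_monotonic_decreasing

    def test_missing_label_rejected(self, two_cluster_population):
        configs, records = two_cluster_population
        result = pca_shapes(gpa(configs))
        with pytest.raises(ValidationError, match="missing"):
            morphospace_summary(result, records[:-1], grouping="skull_class")
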