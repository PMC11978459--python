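"""Surface metric, homologization, group-wise alignment, prototype choice."""

import numpy as np
import pandas as pd
import pytest

from muscleshape import (SurfaceMesh, surface_metric, homologize,
                         average_surface, generalized_align, select_prototype,
                         prototype_sensitivity, generate_muscle_mesh,
                         normalize_pose)
from muscleshape.superimpose import random_rigid_transform


def brute_force_metric(A: np.ndarray, B: np.ndarray) -> float:
    """Independent double-loop oracle for the symmetric surface metric."""
    fwd = np.mean([min(np.sum((a - b) ** 2) for b in B) for a in A])
    bwd = np.mean([min(np.sum((b - a) ** 2) for a in A) for b in B])
    return float(np.sqrt(0.5 * (fwd + bwd)))


def tiny_mesh(vertices: np.ndarray, sid: str = "m") -> SurfaceMesh:
    return SurfaceMesh(sid, vertices, np.zeros((0, 3), dtype=int))


class TestSurfaceMetric:
    def test_identity_is_zero(self, muscle_mesh):
        assert surface_metric(muscle_mesh, muscle_mesh) == 0.0

    def test_uniform_offset(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        B = A + np.array([0.0, 0, 1])
        assert surface_metric(A, B) == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumeration_asymmetric_counts(self):
        A = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        B = np.array([[0.0, 0, 0]])
        # forward mean square (0 + 4)/2 = 2, backward 0 -> sqrt(1/2 * 2) = 1
        assert surface_metric(A, B) == pytest.approx(1.0, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            surface_metric(np.zeros((0, 3)), np.ones((2, 3)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(rng.integers(3, 31), 3))
        B = rng.normal(size=(rng.integers(3, 31), 3))
        assert surface_metric(A, B) == pytest.approx(
            brute_force_metric(A, B), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = rng.normal(size=(12, 3))
        B = rng.normal(size=(9, 3))
        assert surface_metric(A, B) == pytest.approx(
            surface_metric(B, A), abs=1e-12)          # symmetry
        assert surface_metric(A, B) >= 0.0             # nonnegativity
        assert surface_metric(A, A) == 0.0             # identity
        # identity of indiscernibles on vertex sets
        if surface_metric(A, B) == 0.0:
            assert np.allclose(np.sort(A, axis=0), np.sort(B, axis=0))

    def test_invariant_to_common_rigid_transform(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(20, 3))
        B = rng.normal(size=(15, 3))
        T = random_rigid_transform(rng)
        assert surface_metric(T.apply(A), T.apply(B)) == pytest.approx(
            surface_metric(A, B), abs=1e-9)


class TestHomologize:
    def test_identical_meshes(self, muscle_mesh):
        out = homologize(muscle_mesh, muscle_mesh)
        np.testing.assert_array_equal(out, muscle_mesh.vertices)

    def test_small_translation_preserved(self, muscle_mesh):
        from scipy.spatial import cKDTree
        spacing, _ = cKDTree(muscle_mesh.vertices).query(
            muscle_mesh.vertices, k=2)
        delta = 0.3 * spacing[:, 1].min()   # below half the min spacing
        moved = muscle_mesh.with_vertices(
            muscle_mesh.vertices + np.array([delta, 0.0, 0.0]))
        out = homologize(moved, muscle_mesh)
        np.testing.assert_allclose(
            out, muscle_mesh.vertices + [delta, 0, 0], atol=1e-12)

    def test_tie_takes_lowest_index(self):
        sv = np.zeros((8, 3))
        sv[:, 0] = [10, 11, 12, 1, 13, 14, 15, -1]   # v3 and v7 equidistant
        specimen = tiny_mesh(sv, "s")
        prototype = tiny_mesh(np.zeros((1, 3)), "p")
        out = homologize(specimen, prototype)
        np.testing.assert_array_equal(out[0], sv[3])

    def test_empty_specimen_raises(self, muscle_mesh):
        with pytest.raises(ValueError):
            homologize(tiny_mesh(np.zeros((0, 3))), muscle_mesh)


class TestAverageSurface:
    def test_single_identical_specimen(self, muscle_mesh):
        out = average_surface(muscle_mesh, [muscle_mesh.vertices.copy()])
        np.testing.assert_array_equal(out.vertices, muscle_mesh.vertices)
        np.testing.assert_array_equal(out.faces, muscle_mesh.faces)

    def test_symmetric_offsets_cancel(self, muscle_mesh):
        plus = muscle_mesh.vertices + [1.0, 0, 0]
        minus = muscle_mesh.vertices - [1.0, 0, 0]
        out = average_surface(muscle_mesh, [plus, minus])
        np.testing.assert_allclose(out.vertices, muscle_mesh.vertices,
                                   atol=1e-12)

    def test_rowwise_mean(self, muscle_mesh):
        rng = np.random.default_rng(0)
        mats = [muscle_mesh.vertices + rng.normal(size=(muscle_mesh.n_vertices, 3))
                for _ in range(3)]
        out = average_surface(muscle_mesh, mats)
        np.testing.assert_allclose(out.vertices, np.mean(mats, axis=0),
                                   atol=1e-12)

    def test_row_count_mismatch(self, muscle_mesh):
        with pytest.raises(ValueError, match="rows"):
            average_surface(muscle_mesh, [np.zeros((3, 3))])


@pytest.fixture(scope="module")
def identical_population():
    rng = np.random.default_rng(7)
    base = generate_muscle_mesh(250, 60, 30, n_vertices=400,
                                noise_sd=0.5, rng=rng)
    specimens = []
    for i in range(12):
        T = random_rigid_transform(rng, 40.0)
        m = T.apply_mesh(base)
        m.specimen_id = f"S{i:02d}"
        specimens.append(m)
    return base, specimens


@pytest.fixture(scope="module")
def identical_population_result(identical_population):
    _, specimens = identical_population
    return generalized_align(specimens, "S00", unit_scale=False)


class TestGeneralizedAlign:
    def test_exact_recovery_of_identical_shapes(self, identical_population,
                                                identical_population_result):
        base, specimens = identical_population
        res = identical_population_result
        off_diag = res.distances[np.triu_indices(12, 1)]
        assert off_diag.max() < 1e-6
        truth, _ = normalize_pose(base)
        rms = np.sqrt(np.mean(np.sum(
            (res.mean_surface.vertices - truth.vertices) ** 2, axis=1)))
        assert rms < 1e-3

    def test_result_invariants(self, identical_population_result):
        res = identical_population_result
        D = res.distances
        np.testing.assert_allclose(D, D.T, atol=1e-15)
        assert np.all(np.diag(D) == 0.0)
        assert np.all(D >= 0.0)
        # mean surface is the homologized average
        np.testing.assert_allclose(
            res.mean_surface.vertices,
            np.mean(np.stack(res.homologized), axis=0), atol=1e-9)
        for h in res.homologized:
            assert h.shape == (res.mean_surface.n_vertices, 3)

    def test_preconditions(self, identical_population):
        _, specimens = identical_population
        with pytest.raises(ValueError, match="at least 3"):
            generalized_align(specimens[:2], "S00")
        with pytest.raises(ValueError, match="prototype"):
            generalized_align(specimens, "nope")


class TestSelectPrototype:
    IDS = ["s1", "s2", "s3"]
    D = np.array([[0.0, 1, 4], [1, 0, 1], [4, 1, 0]])

    def test_rank_one_lowest_mean(self):
        # row means {2.5, 1.0, 2.5} -> s2
        pid, table = select_prototype([], rank=1, distances=self.D,
                                      ids=self.IDS)
        assert pid == "s2"
        np.testing.assert_allclose(sorted(table["mean_distance"]),
                                   [1.0, 2.5, 2.5])

    def test_rank_two_lexical_tie_break(self):
        pid, _ = select_prototype([], rank=2, distances=self.D, ids=self.IDS)
        assert pid == "s1"

    def test_identical_shapes_lexically_smallest(self):
        D = np.zeros((4, 4))
        pid, _ = select_prototype([], rank=1, distances=D,
                                  ids=["b", "a", "d", "c"])
        assert pid == "a"

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="rank"):
            select_prototype([], rank=4, distances=self.D, ids=self.IDS)

    def test_pairwise_alignment_route(self):
        rng = np.random.default_rng(1)
        specimens = []
        for i, girth in enumerate([-2.0, 0.0, 2.0]):
            m = generate_muscle_mesh(250, 60, 30, girth=girth,
                                     n_vertices=300, rng=rng)
            m.specimen_id = f"g{i}"
            specimens.append(m)
        pid, table = select_prototype(specimens)
        assert pid == "g1"            # the middle shape is most average


@pytest.fixture(scope="module")
def small_population():
    rng = np.random.default_rng(3)
    specimens = []
    for i in range(6):
        m = generate_muscle_mesh(250, 60, 30, girth=rng.normal(),
                                 torsion=rng.normal(),
                                 n_vertices=250, noise_sd=0.3, rng=rng)
        m.specimen_id = f"S{i}"
        specimens.append(m)
    return specimens


class TestPrototypeSensitivity:
    def test_structure_and_reproducibility(self, small_population):
        res = prototype_sensitivity(small_population, k_pcs=4)
        assert res.table.shape == (6, 4)
        assert list(res.table.columns) == ["PC1", "PC2", "PC3", "PC4"]
        assert not res.failures
        assert np.all(res.ranges.to_numpy() >= 0.0)
        assert np.all(np.isfinite(res.ranges.to_numpy()))
        res2 = prototype_sensitivity(small_population, k_pcs=4)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_identical_population_degenerate(self):
        base = generate_muscle_mesh(250, 60, 30, n_vertices=250,
                                    rng=np.random.default_rng(5))
        specimens = []
        for i in range(4):
            m = base.copy()
            m.specimen_id = f"S{i}"
            specimens.append(m)
        res = prototype_sensitivity(specimens, k_pcs=4)
        # no shape variation: no positive eigenvalues anywhere
        np.testing.assert_allclose(res.table.to_numpy(), 0.0, atol=1e-6)
        np.testing.assert_allclose(res.ranges.to_numpy(), 0.0, atol=1e-6)

    def test_invalid_k(self, small_population):
        with pytest.raises(ValueError):
            prototype_sensitivity(small_population, k_pcs=0)


def test_reference_change_decreases_after_burn_in(small_population):
    """The RMS movement of the evolving mean surface shrinks after the
    first couple of outer iterations (the superimposition settles)."""
    res = generalized_align(small_population, small_population[0].specimen_id)
    changes = res.reference_changes
    assert len(changes) >= 3
    assert all(b <= a * 1.05 for a, b in zip(changes[1:], changes[2:]))
    assert changes[-1] < changes[0]
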