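"""Convex-hull volumes, polytope intersection, and the volume-based
beta-diversity partition, against closed-form box algebra and Monte Carlo
rejection sampling."""

import numpy as np
import pytest

from betafacets.functional_beta import (
    DegenerateHullError,
    functional_partition,
    hull_volume,
    intersection_volume,
    pairwise_functional,
    partition_from_volumes,
)
from betafacets.io_tables import OccurrenceMatrix
from betafacets.trait_space import FunctionalSpace

CUBE = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                dtype=float)


def box(lo, hi):
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    return lo + CUBE * (hi - lo)


def mc_intersection(A, B, rng, n=200_000):
    """Rejection-sampling estimate of the hulls' shared volume + its SE."""
    from scipy.spatial import ConvexHull

    ha, hb = ConvexHull(A), ConvexHull(B)
    lo = np.maximum(A.min(axis=0), B.min(axis=0))
    hi = np.minimum(A.max(axis=0), B.max(axis=0))
    if np.any(hi <= lo):
        return 0.0, 0.0
    pts = rng.uniform(lo, hi, size=(n, 3))
    inside = np.ones(n, dtype=bool)
    for h in (ha, hb):
        inside &= (pts @ h.equations[:, :3].T + h.equations[:, 3]
                   <= 1e-12).all(axis=1)
    vol_box = float(np.prod(hi - lo))
    p = inside.mean()
    return vol_box * p, vol_box * np.sqrt(p * (1 - p) / n)


class TestHullVolume:
    def test_unit_cube(self):
        assert hull_volume(CUBE) == pytest.approx(1.0)

    def test_regular_tetrahedron_unit_edge(self):
        # closed form: V = edge^3 / (6 sqrt(2))
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / (2 * np.sqrt(2))  # unit edge
        assert hull_volume(pts) == pytest.approx(np.sqrt(2) / 12)

    def test_interior_point_does_not_change_volume(self):
        pts = np.vstack([CUBE, [[0.5, 0.5, 0.5]]])
        assert hull_volume(pts) == pytest.approx(1.0)

    def test_degenerate_point_set_names_basin(self):
        flat = CUBE.copy()
        flat[:, 2] = 0.0
        with pytest.raises(DegenerateHullError, match="'b7'"):
            hull_volume(flat, label="b7")

    def test_too_few_points(self):
        with pytest.raises(DegenerateHullError, match="at least 4"):
            hull_volume(CUBE[:3])


class TestIntersectionVolume:
    def test_half_shifted_cube(self):
        assert intersection_volume(CUBE, CUBE + [0.5, 0, 0]) == pytest.approx(0.5)

    def test_disjoint_cubes(self):
        assert intersection_volume(CUBE, CUBE + [2.5, 0, 0]) == 0.0

    def test_touching_cubes_share_no_volume(self):
        assert intersection_volume(CUBE, CUBE + [1.0, 0, 0]) == 0.0

    def test_nested_box(self):
        inner = box([0.25, 0.25, 0.25], [0.75, 0.75, 0.75])  # volume 0.125
        assert intersection_volume(CUBE, inner) == pytest.approx(0.125)

    def test_identical_hulls(self):
        assert intersection_volume(CUBE, CUBE) == pytest.approx(1.0)

    def test_monte_carlo_oracle_random_polytopes(self):
        """Exact intersection within 3 SE of rejection sampling."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            A = rng.uniform(0, 1, (12, 3))
            B = rng.uniform(0.3, 1.3, (12, 3))
            exact = intersection_volume(A, B)
            est, se = mc_intersection(A, B, rng)
            assert abs(exact - est) <= max(3 * se, 1e-4)

    def test_bounded_by_smaller_hull(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = rng.uniform(0, 1, (10, 3))
            B = rng.uniform(0.2, 1.2, (10, 3))
            vi = intersection_volume(A, B)
            assert vi <= min(hull_volume(A), hull_volume(B)) + 1e-9

    def test_containment_attains_equality(self):
        inner = box([0.2, 0.3, 0.1], [0.6, 0.8, 0.5])
        vi = intersection_volume(CUBE, inner)
        assert vi == pytest.approx(hull_volume(inner))


class TestFunctionalPartition:
    def test_equal_cubes_half_overlap(self):
        t = functional_partition(CUBE, CUBE + [0.5, 0, 0])
        assert t.beta == pytest.approx(1 / 1.5)
        assert t.turnover == pytest.approx(1 / 1.5)
        assert t.nestedness == pytest.approx(0.0, abs=1e-12)

    def test_nested_boxes_are_pure_nestedness(self):
        inner = box([0.25, 0.25, 0.25], [0.75, 0.75, 0.75])
        t = functional_partition(CUBE, inner)
        assert t.beta == pytest.approx(0.875)
        assert t.turnover == pytest.approx(0.0, abs=1e-12)
        assert t.nestedness == pytest.approx(0.875)

    def test_identical_assemblages_have_zero_beta(self):
        t = functional_partition(CUBE, CUBE)
        assert t.beta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "v1,v2,vi",
        [(1.0, 1.0, 0.5), (1.0, 0.125, 0.125), (2.0, 1.0, 0.3),
         (1.0, 0.7, 0.0), (3.0, 2.0, 1.9)],
    )
    def test_nestedness_residual_matches_closed_form(self, v1, v2, vi):
        """beta - turnover equals the explicit nestedness-resultant term."""
        t = partition_from_volumes(v1, v2, vi)
        closed = (abs(v1 - v2) / (v1 + v2 - vi)) * (vi / (2 * min(v1, v2) - vi))
        assert t.nestedness == pytest.approx(closed, abs=1e-12)

    def test_equal_volumes_imply_zero_nestedness(self):
        t = partition_from_volumes(1.7, 1.7, 0.4)
        assert t.nestedness == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, (10, 3))
        B = rng.uniform(0.3, 1.3, (10, 3))
        s = 2.7
        assert hull_volume(A * s) == pytest.approx(s ** 3 * hull_volume(A))
        t1 = functional_partition(A, B)
        t2 = functional_partition(A * s, B * s)
        assert t1.beta == pytest.approx(t2.beta, rel=1e-9)
        assert t1.turnover == pytest.approx(t2.turnover, rel=1e-9, abs=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(DegenerateHullError):
            partition_from_volumes(0.0, 1.0, 0.0)


class TestPairwiseFunctional:
    def _space_and_occ(self):
        """Three basins whose clouds are hand-placed boxes."""
        # species 0-7: unit cube; 8-15: cube shifted +0.5 in x; 16-23: far cube
        coords = np.vstack([CUBE, CUBE + [0.5, 0, 0], CUBE + [5, 0, 0]])
        species = [f"s{i}" for i in range(24)]
        space = FunctionalSpace(species=species, coordinates=coords,
                                eigenvalues=np.array([3.0, 2.0, 1.0]), m=3)
        values = np.zeros((24, 3), dtype=int)
        values[0:8, 0] = 1
        values[8:16, 1] = 1
        values[16:24, 2] = 1
        occ = OccurrenceMatrix("historical", ["b1", "b2", "b3"], species, values)
        return space, occ

    def test_box_algebra_triples(self):
        space, occ = self._space_and_occ()
        table = pairwise_functional(occ, space)
        by_pair = {p: tuple(v) for p, v in zip(table.basin_pairs, table.values)}
        assert by_pair[("b1", "b2")] == pytest.approx((1 / 1.5, 1 / 1.5, 0.0))
        assert by_pair[("b1", "b3")] == pytest.approx((1.0, 1.0, 0.0))
        assert by_pair[("b2", "b3")] == pytest.approx((1.0, 1.0, 0.0))

    def test_identical_basins_give_zero_beta(self):
        coords = CUBE
        species = [f"s{i}" for i in range(8)]
        space = FunctionalSpace(species=species, coordinates=coords,
                                eigenvalues=np.array([3.0, 2.0, 1.0]), m=3)
        values = np.ones((8, 2), dtype=int)
        occ = OccurrenceMatrix("historical", ["b1", "b2"], species, values)
        table = pairwise_functional(occ, space)
        assert table.values[0] == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_small_basins_listed_before_computation(self):
        space, occ = self._space_and_occ()
        occ.values[1:8, 0] = 0  # basin b1 down to one species
        with pytest.raises(DegenerateHullError, match="b1"):
            pairwise_functional(occ, space)

    def test_drop_small_basins_flag(self):
        space, occ = self._space_and_occ()
        occ.values[1:8, 0] = 0
        table = pairwise_functional(occ, space, drop_small_basins=True)
        assert table.basin_pairs == [("b2", "b3")]

    def test_default_dataset_has_190_functional_pairs(self, default_dataset):
        from betafacets.trait_space import gower_matrix, pcoa_embed

        scenarios, traits, _ = default_dataset
        space = pcoa_embed(gower_matrix(traits), m=3)
        table = pairwise_functional(scenarios["historical"], space)
        assert table.n_pairs == 190
        assert np.all(table.values >= -1e-12)
        assert np.all(table.values <= 1 + 1e-12)
        assert np.allclose(table.beta, table.turnover + table.nestedness,
                           atol=1e-12)
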