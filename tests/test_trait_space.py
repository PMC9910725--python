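"""Gower distances and principal-coordinates embedding, cross-checked
against hand arithmetic and scikit-bio's PCoA."""

import numpy as np
import pandas as pd
import pytest

from betafacets.trait_space import (
    DegenerateSpaceError,
    DissimilarityMatrix,
    TraitTable,
    gower_matrix,
    pcoa_embed,
    read_trait_table,
    space_quality,
)


def table_from(data: dict, species=None) -> TraitTable:
    species = species or [f"s{i}" for i in range(len(next(iter(data.values()))))]
    df = pd.DataFrame(data, index=pd.Index(species, name="species_id"))
    return TraitTable(species=species, data=df.astype(float))


class TestGower:
    def test_identical_species_have_zero_distance(self):
        t = table_from({"body_length": [10, 10, 25], "migration": [2, 2, 4],
                        "diet": [1, 1, 3], "water_column": [1, 1, 2],
                        "fecundity": [2, 2, 3]})
        d = gower_matrix(t)
        assert d.values[0, 1] == 0.0

    def test_single_trait_half_range_contributes_tenth(self):
        # two species differ only in body length, by half the observed range
        t = table_from({"body_length": [10.0, 20.0, 30.0],
                        "migration": [3, 3, 3], "diet": [2, 2, 2],
                        "water_column": [1, 1, 1], "fecundity": [2, 2, 2]})
        d = gower_matrix(t)
        assert d.values[0, 1] == pytest.approx(0.5 / 5)

    def test_hand_computed_three_species_matrix(self, toy_traits):
        d = gower_matrix(toy_traits)
        # ranges: length 20, migration 4, diet 2, water 1, fecundity 3
        d01 = (10 / 20 + 2 / 4 + 0 + 1 + 0) / 5
        d02 = (20 / 20 + 4 / 4 + 2 / 2 + 1 + 3 / 3) / 5
        d12 = (10 / 20 + 2 / 4 + 2 / 2 + 0 + 3 / 3) / 5
        assert d.values[0, 1] == pytest.approx(d01)
        assert d.values[0, 2] == pytest.approx(d02)
        assert d.values[1, 2] == pytest.approx(d12)

    def test_zero_range_trait_warns_and_contributes_nothing(self, caplog):
        t = table_from({"body_length": [10, 20], "migration": [1, 5],
                        "diet": [2, 2], "water_column": [1, 2],
                        "fecundity": [1, 4]})
        with caplog.at_level("WARNING"):
            d = gower_matrix(t)
        assert "zero range" in caplog.text
        assert d.values[0, 1] == pytest.approx((1 + 1 + 0 + 1 + 1) / 5)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"body_length": [1.0, np.nan], "migration": [1, 2],
                           "diet": [1, 2], "water_column": [1, 2],
                           "fecundity": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            TraitTable(species=["a", "b"], data=df)

    def test_permutation_equivariance(self, default_dataset):
        _, traits, _ = default_dataset
        d = gower_matrix(traits)
        perm = np.random.default_rng(0).permutation(len(traits.species))
        species = [traits.species[i] for i in perm]
        shuffled = TraitTable(species=species, data=traits.data.loc[species])
        d2 = gower_matrix(shuffled)
        assert np.allclose(d2.values, d.values[np.ix_(perm, perm)])

    def test_ordinal_range_validation(self):
        with pytest.raises(ValueError, match="water_column"):
            table_from({"body_length": [1, 2], "migration": [1, 2],
                        "diet": [1, 2], "water_column": [1, 3],
                        "fecundity": [1, 2]})

    def test_csv_roundtrip(self, toy_traits, tmp_path):
        p = tmp_path / "traits.csv"
        toy_traits.write_csv(p)
        back = read_trait_table(p)
        assert back.species == toy_traits.species
        assert np.allclose(back.data.values, toy_traits.data.values)


class TestPCoA:
    def test_two_points_embed_at_plus_minus_half_delta(self):
        delta = 0.7
        d = DissimilarityMatrix(["a", "b"],
                                np.array([[0, delta], [delta, 0.0]]))
        space = pcoa_embed(d, m=1)
        assert sorted(space.coordinates[:, 0]) == pytest.approx(
            [-delta / 2, delta / 2])

    def test_equilateral_triangle_closed_form(self):
        d = DissimilarityMatrix(
            ["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        space = pcoa_embed(d, m=2)
        assert space.eigenvalues[0] == pytest.approx(space.eigenvalues[1])
        from scipy.spatial.distance import pdist
        assert pdist(space.coordinates) == pytest.approx(np.ones(3))

    def test_full_dimension_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform
        d = DissimilarityMatrix([f"s{i}" for i in range(8)],
                                squareform(pdist(pts)))
        space = pcoa_embed(d, m=3)
        assert pdist(space.coordinates) == pytest.approx(
            squareform(d.values), abs=1e-8)

    def test_m_beyond_positive_eigenvalues_errors(self):
        d = DissimilarityMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(DegenerateSpaceError, match="1 positive"):
            pcoa_embed(d, m=2)

    def test_embedding_is_centred_and_deterministic(self, default_dataset):
        _, traits, _ = default_dataset
        d = gower_matrix(traits)
        s1 = pcoa_embed(d, m=3)
        s2 = pcoa_embed(d, m=3)
        assert np.allclose(s1.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert np.array_equal(s1.coordinates, s2.coordinates)
        assert np.all(np.diff(s1.eigenvalues) <= 1e-12)
        assert np.all(s1.eigenvalues > 0)

    def test_agrees_with_scikit_bio_pcoa(self, default_dataset):
        """Independent oracle: skbio's classical scaling, up to axis sign."""
        skbio = pytest.importorskip("skbio")
        _, traits, _ = default_dataset
        d = gower_matrix(traits)
        ours = pcoa_embed(d, m=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.species))
        ref_coords = ref.samples.values[:, :3]
        ref_eigs = ref.eigvals.values[:3]
        assert ours.eigenvalues == pytest.approx(ref_eigs, rel=1e-6)
        for k in range(3):
            col, refcol = ours.coordinates[:, k], ref_coords[:, k]
            sign = 1.0 if np.dot(col, refcol) >= 0 else -1.0
            assert col == pytest.approx(sign * refcol, abs=1e-6)

    def test_lingoes_correction_removes_negative_eigenvalues(self, default_dataset):
        _, traits, _ = default_dataset
        d = gower_matrix(traits)
        n = len(d.species)
        space = pcoa_embed(d, m=n - 2, correction="lingoes")
        assert np.all(space.eigenvalues > 0)


class TestSpaceQuality:
    def test_perfect_embedding_has_zero_deviation(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform
        d = DissimilarityMatrix([f"s{i}" for i in range(6)],
                                squareform(pdist(pts)))
        space = pcoa_embed(d, m=3)
        assert space_quality(d, space) == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_triangle_on_one_axis_has_residual(self):
        d = DissimilarityMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        q1 = space_quality(d, pcoa_embed(d, m=1))
        q2 = space_quality(d, pcoa_embed(d, m=2))
        assert q1 > 0
        assert q2 == pytest.approx(0.0, abs=1e-12)

    def test_quality_non_increasing_in_m(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform
        d = DissimilarityMatrix([f"s{i}" for i in range(10)],
                                squareform(pdist(pts)))
        qs = [space_quality(d, pcoa_embed(d, m=m)) for m in (1, 2, 3, 4)]
        assert all(qs[i + 1] <= qs[i] + 1e-12 for i in range(3))
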