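"""Built-in bradykinin models, distance-geometry embedding, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phorescreen.featperc import FeatureType
from phorescreen.geometry import pairwise_distances
from phorescreen.phmodel import (
    ModelValidationError,
    PharmacophoreModel,
    PharmacophorePoint,
    builtin_model,
    embed_model,
    model_from_text,
    model_to_text,
)


def trilaterate_consensus():
    """Independent placement of the four consensus points from the six distances.

    P1 at the origin, P2 on the x-axis, P3 in the xy-plane, P4 solved from
    its three sphere equations.
    """
    d12, d13, d14 = 9.0, 14.0, 10.5
    d23, d24, d34 = 6.0, 7.0, 7.5
    p1 = np.zeros(3)
    p2 = np.array([d12, 0.0, 0.0])
    x3 = (d12**2 + d13**2 - d23**2) / (2 * d12)
    y3 = np.sqrt(d13**2 - x3**2)
    p3 = np.array([x3, y3, 0.0])
    x4 = (d12**2 + d14**2 - d24**2) / (2 * d12)
    y4 = (d13**2 + d14**2 - d34**2 - 2 * x3 * x4) / (2 * y3)
    z4sq = d14**2 - x4**2 - y4**2
    assert z4sq > 0
    p4 = np.array([x4, y4, np.sqrt(z4sq)])
    return np.array([p1, p2, p3, p4])


class TestBuiltinModels:
    def test_consensus_points_and_distances(self, bk_consensus):
        m = bk_consensus
        assert m.labels == ["P1", "P2", "P3", "P4"]
        assert m.distance("P1", "P2") == 9.0
        assert m.distance("P1", "P3") == 14.0
        assert m.distance("P1", "P4") == 10.5
        assert m.distance("P2", "P3") == 6.0
        assert m.distance("P2", "P4") == 7.0
        assert m.distance("P3", "P4") == 7.5
        assert m.points[0].accepted_types == {FeatureType.POSITIVE}
        assert m.points[1].accepted_types == {FeatureType.DONOR, FeatureType.ACCEPTOR}
        assert m.points[2].accepted_types == {FeatureType.AROMATIC}

    def test_b1_p5_row(self):
        m = builtin_model("bk_b1")
        assert m.labels[-1] == "P5"
        assert m.distance("P1", "P5") == 9.5
        assert m.distance("P2", "P5") == 9.3
        assert m.distance("P3", "P5") == 9.5
        assert m.distance("P4", "P5") == 5.7
        assert m.points[-1].accepted_types == {FeatureType.ACCEPTOR}

    def test_b2_p5_row(self):
        m = builtin_model("bk_b2")
        assert m.distance("P1", "P5") == 11.0
        assert m.distance("P2", "P5") == 9.0
        assert m.distance("P3", "P5") == 8.8
        assert m.distance("P4", "P5") == 8.4
        assert m.points[-1].accepted_types == {
            FeatureType.HYDROPHOBIC,
            FeatureType.AROMATIC,
        }

    def test_p5_pairs_carry_wider_tolerance(self):
        m = builtin_model("bk_b1")
        assert m.pair_tolerance(0, 4) == pytest.approx(2.0)
        assert m.pair_tolerance(0, 1) == pytest.approx(1.5)

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="bk_consensus"):
            builtin_model("x")


class TestEmbedding:
    def test_consensus_matches_trilateration_oracle(self, bk_consensus):
        result = embed_model(bk_consensus, mode="strict")
        assert result.realizable
        assert result.max_residual <= 1e-6
        oracle = trilaterate_consensus()
        assert np.allclose(
            pairwise_distances(result.coordinates), pairwise_distances(oracle), atol=1e-6
        )

    def test_consensus_realizes_all_printed_distances(self, bk_consensus, consensus_embedding):
        realized = consensus_embedding.realized_distances()
        assert np.abs(realized - bk_consensus.target_distances).max() <= 1e-6

    def test_b1_p5_out_of_plane_is_imaginary(self):
        """Trilaterating P5 against P1, P2, P3 forces z^2 < 0 for the B1 set."""
        base = trilaterate_consensus()
        d15, d25, d35 = 9.5, 9.3, 9.5
        d12 = 9.0
        x5 = (d12**2 + d15**2 - d25**2) / (2 * d12)
        x3, y3 = base[2, 0], base[2, 1]
        y5 = (d15**2 + x3**2 + y3**2 - d35**2 - 2 * x3 * x5) / (2 * y3)
        z5sq = d15**2 - x5**2 - y5**2
        assert z5sq < 0

    @pytest.mark.parametrize("name", ["bk_b1", "bk_b2"])
    def test_five_point_sets_not_realizable(self, name):
        result = embed_model(builtin_model(name), mode="strict")
        assert not result.realizable
        ls = embed_model(builtin_model(name), mode="least_squares")
        assert not ls.realizable
        assert ls.max_residual <= result.max_residual + 1e-12
        assert np.isfinite(ls.coordinates).all()

    def test_two_point_model_embeds(self):
        pts = [
            PharmacophorePoint("A", frozenset({FeatureType.DONOR})),
            PharmacophorePoint("B", frozenset({FeatureType.ACCEPTOR})),
        ]
        m = PharmacophoreModel("pair", pts, np.array([[0.0, 5.0], [5.0, 0.0]]))
        r = embed_model(m, mode="strict")
        assert r.realizable
        assert np.linalg.norm(r.coordinates[0] - r.coordinates[1]) == pytest.approx(5.0)

    def test_coordinates_centered(self, consensus_embedding):
        assert np.allclose(consensus_embedding.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_permutation_invariance(self, bk_consensus):
        rng = np.random.default_rng(0)
        perm = rng.permutation(4)
        m2 = PharmacophoreModel(
            "perm",
            [bk_consensus.points[i] for i in perm],
            bk_consensus.target_distances[np.ix_(perm, perm)],
        )
        d1 = pairwise_distances(embed_model(bk_consensus, "strict").coordinates)
        d2 = pairwise_distances(embed_model(m2, "strict").coordinates)
        assert np.allclose(d2, d1[np.ix_(perm, perm)], atol=1e-9)

    @given(st.integers(0, 10_000), st.integers(2, 6))
    @settings(max_examples=30, deadline=None)
    def test_random_point_sets_recovered(self, seed, n):
        """Distances generated from real 3D points are always recovered."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-8, 8, size=(n, 3))
        d = pairwise_distances(pts)
        if np.any(d[~np.eye(n, dtype=bool)] < 1e-3):
            return  # degenerate draw: coincident points
        model = PharmacophoreModel(
            "rand",
            [
                PharmacophorePoint(f"Q{i}", frozenset({FeatureType.DONOR}), 1.0)
                for i in range(n)
            ],
            d,
            default_tolerance=float(d.max()),
        )
        r = embed_model(model, mode="strict")
        assert r.realizable
        assert r.max_residual <= 1e-6


class TestModelValidation:
    def test_asymmetric_matrix_rejected(self):
        pts = [
            PharmacophorePoint("A", frozenset({FeatureType.DONOR})),
            PharmacophorePoint("B", frozenset({FeatureType.DONOR})),
        ]
        with pytest.raises(ModelValidationError, match="symmetric"):
            PharmacophoreModel("bad", pts, np.array([[0.0, 5.0], [4.0, 0.0]]))

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ModelValidationError, match="tolerance"):
            PharmacophorePoint("A", frozenset({FeatureType.DONOR}), tolerance=-1.0)

    def test_triangle_violation_rejected(self):
        pts = [
            PharmacophorePoint("A", frozenset({FeatureType.DONOR})),
            PharmacophorePoint("B", frozenset({FeatureType.DONOR})),
            PharmacophorePoint("C", frozenset({FeatureType.DONOR})),
        ]
        d = np.array([[0.0, 1.0, 30.0], [1.0, 0.0, 1.0], [30.0, 1.0, 0.0]])
        with pytest.raises(ModelValidationError, match="triangle"):
            PharmacophoreModel("bad", pts, d)


class TestSerialization:
    @pytest.mark.parametrize("name", ["bk_consensus", "bk_b1", "bk_b2"])
    def test_round_trip(self, name):
        m = builtin_model(name)
        back = model_from_text(model_to_text(m))
        assert back.name == m.name
        assert back.labels == m.labels
        assert [p.accepted_types for p in back.points] == [p.accepted_types for p in m.points]
        assert [p.tolerance for p in back.points] == [p.tolerance for p in m.points]
        assert np.array_equal(back.target_distances, m.target_distances)
        if name == "bk_b2":
            assert back.distance("P1", "P5") == 11.0

    def test_asymmetric_text_rejected(self):
        text = model_to_text(builtin_model("bk_consensus")).replace("14.0", "13.0", 1)
        with pytest.raises(ModelValidationError):
            model_from_text(text)

    def test_negative_tolerance_text_rejected(self):
        text = model_to_text(builtin_model("bk_consensus")).replace(
            '"tolerance": 1.5', '"tolerance": -1', 1
        )
        with pytest.raises(ModelValidationError, match="tolerance"):
            model_from_text(text)

    def test_unknown_feature_type_rejected(self):
        text = model_to_text(builtin_model("bk_consensus")).replace("POSITIVE", "MAGIC")
        with pytest.raises(ModelValidationError, match="accepted_types"):
            model_from_text(text)

    def test_bad_version_rejected(self):
        text = model_to_text(builtin_model("bk_consensus")).replace(
            '"version": 1', '"version": 99'
        )
        with pytest.raises(ModelValidationError, match="version"):
            model_from_text(text)
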