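import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from phorescreen.chemio import fixture_library, parse_smiles
from phorescreen.featperc import FeaturePoint, FeatureType
from phorescreen.phmodel import builtin_model, embed_model


@pytest.fixture(scope="session")
def bk_consensus():
    return builtin_model("bk_consensus")


@pytest.fixture(scope="session")
def consensus_embedding(bk_consensus):
    return embed_model(bk_consensus, mode="strict")


@pytest.fixture(scope="session")
def fixture_lib():
    """Eight hit drugs plus five seeded decoys."""
    return fixture_library(n_decoys=5, seed=42)


@pytest.fixture
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


def consensus_features(coords: np.ndarray) -> list[FeaturePoint]:
    """Synthetic features typed to satisfy P1-P4 at the given positions."""
    types = [
        FeatureType.POSITIVE,
        FeatureType.DONOR,
        FeatureType.AROMATIC,
        FeatureType.ACCEPTOR,
    ]
    return [
        FeaturePoint(t, tuple(xyz), (i,))
        for i, (t, xyz) in enumerate(zip(types, coords))
    ]


def random_instance(rng: np.random.Generator):
    """A random (features, model) matching instance for oracle cross-checks."""
    from phorescreen.phmodel import PharmacophoreModel, PharmacophorePoint

    n_points = int(rng.integers(2, 6))
    n_feats = int(rng.integers(0, 9))
    all_types = list(FeatureType)
    pts = []
    for i in range(n_points):
        k = int(rng.integers(1, 3))
        accepted = frozenset(rng.choice(all_types, size=k, replace=False).tolist())
        pts.append(PharmacophorePoint(f"Q{i}", accepted, float(rng.uniform(0.5, 2.5))))
    ref = rng.uniform(-6, 6, size=(n_points, 3))
    diff = ref[:, None, :] - ref[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    # keep off-diagonal strictly positive
    dmat += 1e-6 * (1 - np.eye(n_points))
    model = PharmacophoreModel(
        name="random", points=pts, target_distances=dmat, default_tolerance=2.0
    )
    feats = [
        FeaturePoint(
            all_types[int(rng.integers(len(all_types)))],
            tuple(rng.uniform(-6, 6, size=3)),
            (i,),
        )
        for i in range(n_feats)
    ]
    return feats, model
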