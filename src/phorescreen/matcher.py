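"""Correspondence search between ligand features and a pharmacophore model.

Matching is defined purely on distances: an injective, type-compatible
assignment of model points to perceived features is a correspondence when
every pairwise feature distance deviates from its model target by at most
the pair tolerance.  The model is never embedded during matching, which
makes the search reflection-invariant and insensitive to the exact 3D
realizability of the model's distance matrix.

The production search is a backtracking enumeration with pairwise distance
pruning; :func:`brute_force_match` is a deliberately naive permutation
oracle kept for cross-checking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .featperc import FeaturePoint, FeatureRules, perceive_features
from .geometry import kabsch_superpose, pairwise_distances
from .phmodel import PharmacophoreModel, embed_model

if TYPE_CHECKING:  # pragma: no cover
    from .confgen import ConformerEnsemble

__all__ = [
    "Correspondence",
    "MatchResult",
    "match_conformer",
    "brute_force_match",
    "match_molecule",
    "kabsch_superpose",
]


@dataclass(frozen=True)
class Correspondence:
    """An injective assignment of model point labels to feature indices."""

    mapping: tuple[tuple[str, int], ...]  # (label, feature index), model order
    deviations: tuple[tuple[str, str, float], ...]  # (label_i, label_j, |Δd|)

    @property
    def feature_indices(self) -> tuple[int, ...]:
        return tuple(idx for _, idx in self.mapping)

    @property
    def max_deviation(self) -> float:
        return max((d for *_, d in self.deviations), default=0.0)

    @property
    def sum_sq_deviation(self) -> float:
        return sum(d * d for *_, d in self.deviations)

    def as_dict(self) -> dict[str, int]:
        return dict(self.mapping)


@dataclass
class MatchResult:
    """Outcome of matching one molecule (all conformers) against one model."""

    matched: bool
    molecule_name: str
    model_name: str
    best_conformer: int | None = None
    best_correspondence: Correspondence | None = None
    max_deviation: float = float("nan")
    sum_sq_deviation: float = float("nan")
    superposition_rmsd: float = float("nan")

    def __post_init__(self) -> None:
        if self.matched != (self.best_correspondence is not None):
            raise ValueError("matched flag inconsistent with best_correspondence")


def _compatible(model: PharmacophoreModel, features: Sequence[FeaturePoint]) -> list[list[int]]:
    return [
        [k for k, f in enumerate(features) if f.type in p.accepted_types]
        for p in model.points
    ]


def _build_correspondence(
    model: PharmacophoreModel, assignment: dict[int, int], dmat: np.ndarray
) -> Correspondence:
    labels = model.labels
    mapping = tuple((labels[i], assignment[i]) for i in range(len(labels)))
    devs = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        dev = abs(dmat[assignment[i], assignment[j]] - model.target_distances[i, j])
        devs.append((labels[i], labels[j], float(dev)))
    return Correspondence(mapping=mapping, deviations=tuple(devs))


def _sorted_correspondences(
    model: PharmacophoreModel, results: list[Correspondence]
) -> list[Correspondence]:
    return sorted(results, key=lambda c: (c.sum_sq_deviation, c.feature_indices))


def match_conformer(
    features: Sequence[FeaturePoint],
    model: PharmacophoreModel,
    tolerance: float | None = None,
) -> list[Correspondence]:
    """All tolerance-satisfying correspondences for one conformer's features.

    Backtracking over model points ordered by fewest compatible features,
    pruning each partial assignment on every newly closed point pair.
    ``tolerance`` overrides every pair tolerance when given.  Results are
    sorted by ascending sum of squared deviations, ties broken by the
    feature-index tuple in model-point order.
    """
    n_points = len(model.points)
    if n_points == 0 or not features:
        return []
    dmat = pairwise_distances(np.array([f.xyz for f in features]))
    compat = _compatible(model, features)
    if any(not c for c in compat):
        return []
    order = sorted(range(n_points), key=lambda i: (len(compat[i]), i))

    def tol(i: int, j: int) -> float:
        return tolerance if tolerance is not None else model.pair_tolerance(i, j)

    results: list[Correspondence] = []
    assignment: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(depth: int) -> None:
        if depth == n_points:
            results.append(_build_correspondence(model, assignment, dmat))
            return
        i = order[depth]
        for k in compat[i]:
            if k in used:
                continue
            ok = True
            for j in assignment:
                dev = abs(dmat[k, assignment[j]] - model.target_distances[i, j])
                if dev > tol(i, j):
                    ok = False
                    break
            if ok:
                assignment[i] = k
                used.add(k)
                backtrack(depth + 1)
                used.discard(k)
                del assignment[i]

    backtrack(0)
    return _sorted_correspondences(model, results)


_BRUTE_FORCE_GUARD = 10


def brute_force_match(
    features: Sequence[FeaturePoint],
    model: PharmacophoreModel,
    tolerance: float | None = None,
) -> list[Correspondence]:
    """Exhaustive permutation oracle; identical result set to match_conformer.

    Guarded to at most 10 features to keep enumeration tractable.
    """
    if len(features) > _BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute_force_match guard exceeded: {len(features)} features > {_BRUTE_FORCE_GUARD}"
        )
    n_points = len(model.points)
    if n_points == 0 or len(features) < n_points:
        return []
    dmat = pairwise_distances(np.array([f.xyz for f in features]))

    def tol(i: int, j: int) -> float:
        return tolerance if tolerance is not None else model.pair_tolerance(i, j)

    results: list[Correspondence] = []
    for perm in itertools.permutations(range(len(features)), n_points):
        if any(
            features[perm[i]].type not in model.points[i].accepted_types
            for i in range(n_points)
        ):
            continue
        ok = True
        for i, j in itertools.combinations(range(n_points), 2):
            if abs(dmat[perm[i], perm[j]] - model.target_distances[i, j]) > tol(i, j):
                ok = False
                break
        if ok:
            assignment = {i: perm[i] for i in range(n_points)}
            results.append(_build_correspondence(model, assignment, dmat))
    return _sorted_correspondences(model, results)


def match_molecule(
    ensemble: "ConformerEnsemble",
    model: PharmacophoreModel,
    tolerance: float | None = None,
    rules: FeatureRules | None = None,
) -> MatchResult:
    """Match every conformer of an ensemble against a model.

    The best correspondence minimizes the sum of squared distance deviations
    over all (conformer, correspondence) pairs; ties go to the lowest
    conformer index.  The superposition RMSD aligns the matched feature
    positions onto the model's least-squares embedding with a proper Kabsch
    fit; it is diagnostic only and never a match criterion.
    """
    mol = ensemble.molecule
    best: tuple[float, int, Correspondence, np.ndarray] | None = None
    for k, xyz in enumerate(ensemble.conformers):
        feats = perceive_features(mol, coords=xyz, rules=rules)
        for corr in match_conformer(feats, model, tolerance=tolerance):
            key = corr.sum_sq_deviation
            if best is None or key < best[0]:
                positions = np.array([feats[i].xyz for i in corr.feature_indices])
                best = (key, k, corr, positions)
    if best is None:
        return MatchResult(matched=False, molecule_name=mol.name, model_name=model.name)
    _, conf_idx, corr, positions = best
    embedding = embed_model(model, mode="least_squares")
    rmsd = kabsch_superpose(positions, embedding.coordinates)[2]
    return MatchResult(
        matched=True,
        molecule_name=mol.name,
        model_name=model.name,
        best_conformer=conf_idx,
        best_correspondence=corr,
        max_deviation=corr.max_deviation,
        sum_sq_deviation=corr.sum_sq_deviation,
        superposition_rmsd=rmsd,
    )
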