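"""Pharmacophore models: data structure, built-in bradykinin models, embedding.

A pharmacophore model is an ordered set of labeled points, each accepting one
or more feature types, plus a symmetric matrix of target inter-point
distances in Å.  Three models ship with the package:

``bk_consensus``
    The four points common to the bradykinin B1 and B2 receptor
    pharmacophores — a positive charge (P1), a hydrogen-bond donor/acceptor
    (P2), an aromatic ring (P3) and a second donor/acceptor (P4) — with the
    six consensus distances d(1,2)=9, d(1,3)=14, d(1,4)=10.5, d(2,3)=6,
    d(2,4)=7, d(3,4)=7.5 Å.  Ligands matching these four points are
    candidate non-selective antagonists.

``bk_b1`` / ``bk_b2``
    The consensus points plus the receptor-discriminating fifth point P5:
    a hydrogen-bond acceptor for B1 (d(1,5)=9.5, d(2,5)=9.3, d(3,5)=9.5,
    d(4,5)=5.7 Å) and a hydrophobic/aromatic moiety for B2 (d(1,5)=11,
    d(2,5)=9, d(3,5)=8.8, d(4,5)=8.4 Å).

The five-point distance sets are NOT exactly realizable in 3D (the centered
Gram matrix acquires a negative eigenvalue); matching therefore never embeds
the model but compares distance matrices directly, and the embedding here
serves as a diagnostic and visualization aid only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares as _lsq

from .featperc import FeatureType

__all__ = [
    "PharmacophorePoint",
    "PharmacophoreModel",
    "EmbeddingResult",
    "ModelValidationError",
    "builtin_model",
    "BUILTIN_MODEL_NAMES",
    "embed_model",
    "model_to_text",
    "model_from_text",
]

_FORMAT_TAG = "phorescreen-model"
_FORMAT_VERSION = 1


class ModelValidationError(ValueError):
    """Raised when a model definition violates its schema or invariants."""


@dataclass(frozen=True)
class PharmacophorePoint:
    """One labeled model point with its accepted feature types and tolerance (Å)."""

    label: str
    accepted_types: frozenset[FeatureType]
    tolerance: float = 1.5

    def __post_init__(self) -> None:
        if not self.accepted_types:
            raise ModelValidationError(f"point {self.label!r}: empty accepted_types")
        if self.tolerance <= 0:
            raise ModelValidationError(
                f"point {self.label!r}: tolerance must be > 0, got {self.tolerance}"
            )


@dataclass
class PharmacophoreModel:
    """Labeled points plus a symmetric target-distance matrix in Å."""

    name: str
    points: list[PharmacophorePoint]
    target_distances: np.ndarray
    default_tolerance: float = 1.5

    def __post_init__(self) -> None:
        self.target_distances = np.asarray(self.target_distances, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.points)
        labels = [p.label for p in self.points]
        if len(set(labels)) != n:
            raise ModelValidationError(f"duplicate point labels in {labels}")
        d = self.target_distances
        if d.shape != (n, n):
            raise ModelValidationError(
                f"target_distances shape {d.shape} does not match {n} points"
            )
        if not np.allclose(d, d.T, atol=0.0):
            raise ModelValidationError("target_distances: matrix not symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ModelValidationError("target_distances: nonzero diagonal")
        off = d[~np.eye(n, dtype=bool)]
        if n > 1 and np.any(off <= 0):
            raise ModelValidationError("target_distances: non-positive off-diagonal entry")
        if self.default_tolerance <= 0:
            raise ModelValidationError("default_tolerance must be > 0")
        # Triangle inequality, slack 2x the default tolerance.
        slack = 2.0 * self.default_tolerance
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if i != j and j != k and i != k:
                        if d[i, k] > d[i, j] + d[j, k] + slack:
                            raise ModelValidationError(
                                f"triangle inequality violated beyond {slack} Å for "
                                f"({labels[i]}, {labels[j]}, {labels[k]})"
                            )

    # -- lookups ------------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def distance(self, a: str, b: str) -> float:
        return float(self.target_distances[self.index(a), self.index(b)])

    def pair_tolerance(self, i: int, j: int) -> float:
        """Tolerance for a point pair: the larger of the two point tolerances."""
        return max(self.points[i].tolerance, self.points[j].tolerance)


# ---------------------------------------------------------------------------
# Built-in bradykinin models
# ---------------------------------------------------------------------------

BUILTIN_MODEL_NAMES = ("bk_consensus", "bk_b1", "bk_b2")

# Consensus distances between the four common points (Å).
_CONSENSUS = {
    ("P1", "P2"): 9.0,
    ("P1", "P3"): 14.0,
    ("P1", "P4"): 10.5,
    ("P2", "P3"): 6.0,
    ("P2", "P4"): 7.0,
    ("P3", "P4"): 7.5,
}
# Receptor-specific distances from P5 to each consensus point (Å).
_B1_P5 = {"P1": 9.5, "P2": 9.3, "P3": 9.5, "P4": 5.7}
_B2_P5 = {"P1": 11.0, "P2": 9.0, "P3": 8.8, "P4": 8.4}

_DA = frozenset({FeatureType.DONOR, FeatureType.ACCEPTOR})
# P5 pairs carry a wider tolerance because the five-point distance sets are
# consensus values that are not exactly realizable in 3D.
_P5_TOLERANCE = 2.0


def _consensus_points(tol: float) -> list[PharmacophorePoint]:
    return [
        PharmacophorePoint("P1", frozenset({FeatureType.POSITIVE}), tol),
        PharmacophorePoint("P2", _DA, tol),
        PharmacophorePoint("P3", frozenset({FeatureType.AROMATIC}), tol),
        PharmacophorePoint("P4", _DA, tol),
    ]


def _matrix(labels: list[str], pairs: dict[tuple[str, str], float]) -> np.ndarray:
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return d


def builtin_model(name: str, default_tolerance: float = 1.5) -> PharmacophoreModel:
    """Return one of the built-in bradykinin pharmacophore models.

    ``bk_consensus`` has the four common points P1–P4; ``bk_b1`` and
    ``bk_b2`` add the receptor-discriminating P5 (acceptor for B1,
    hydrophobic/aromatic for B2) with its printed distance row.
    """
    if name not in BUILTIN_MODEL_NAMES:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(BUILTIN_MODEL_NAMES)}"
        )
    points = _consensus_points(default_tolerance)
    pairs = dict(_CONSENSUS)
    if name == "bk_b1":
        points.append(
            PharmacophorePoint("P5", frozenset({FeatureType.ACCEPTOR}), _P5_TOLERANCE)
        )
        pairs.update({(k, "P5"): v for k, v in _B1_P5.items()})
    elif name == "bk_b2":
        points.append(
            PharmacophorePoint(
                "P5",
                frozenset({FeatureType.HYDROPHOBIC, FeatureType.AROMATIC}),
                _P5_TOLERANCE,
            )
        )
        pairs.update({(k, "P5"): v for k, v in _B2_P5.items()})
    labels = [p.label for p in points]
    return PharmacophoreModel(
        name=name,
        points=points,
        target_distances=_matrix(labels, pairs),
        default_tolerance=default_tolerance,
    )


# ---------------------------------------------------------------------------
# Distance-geometry embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingResult:
    """3D coordinates realizing (exactly or approximately) a distance matrix.

    ``realizable`` is True iff the doubly-centered Gram matrix of the squared
    distances is positive semidefinite of rank <= 3 (up to a relative
    eigenvalue tolerance) and the realized distances reproduce the targets to
    within 1e-6 Å.  Coordinates are centered on the origin.
    """

    coordinates: np.ndarray
    realizable: bool
    max_residual: float
    gram_eigenvalues: np.ndarray

    def realized_distances(self) -> np.ndarray:
        x = self.coordinates
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


_EIG_RTOL = 1e-8
_STRICT_RESIDUAL = 1e-6


def _classical_mds(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Torgerson MDS: coordinates from the doubly-centered Gram matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(gram)  # ascending
    order = np.argsort(evals)[::-1]
    evals_sorted = evals[order]
    evecs = evecs[:, order]
    scale = max(abs(evals_sorted[0]), 1.0)
    n_pos = int(np.sum(evals_sorted > _EIG_RTOL * scale))
    psd_rank3 = n_pos <= 3 and evals_sorted[-1] >= -_EIG_RTOL * scale
    k = min(3, n - 1) if n > 1 else 1
    top = np.clip(evals_sorted[:k], 0.0, None)
    coords = np.zeros((n, 3))
    coords[:, :k] = evecs[:, :k] * np.sqrt(top)
    coords -= coords.mean(axis=0)
    return coords, evals_sorted, psd_rank3


def _refine_least_squares(d: np.ndarray, x0: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)

    def resid(flat: np.ndarray) -> np.ndarray:
        x = flat.reshape(n, 3)
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1) + 1e-300)
        return (dist - d)[iu]

    sol = _lsq(resid, x0.ravel(), method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    x = sol.x.reshape(n, 3)
    return x - x.mean(axis=0)


def embed_model(model: PharmacophoreModel, mode: str = "strict") -> EmbeddingResult:
    """Embed a model's distance matrix in 3D.

    ``strict`` performs classical multidimensional scaling and flags whether
    the matrix is exactly realizable in 3D; a non-realizable matrix returns
    ``realizable=False`` with diagnostics rather than raising.
    ``least_squares`` additionally refines the MDS coordinates to minimize
    the sum of squared distance residuals, reporting the residual honestly.
    """
    if mode not in ("strict", "least_squares"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    d = model.target_distances
    coords, evals, psd_rank3 = _classical_mds(d)
    if mode == "least_squares" and d.shape[0] > 1:
        coords = _refine_least_squares(d, coords)
    diff = coords[:, None, :] - coords[None, :, :]
    realized = np.sqrt((diff**2).sum(axis=-1))
    max_residual = float(np.abs(realized - d).max())
    if mode == "strict":
        realizable = psd_rank3 and max_residual <= _STRICT_RESIDUAL
    else:
        # Realizability is a property of the matrix, judged as in strict mode.
        strict_coords, _, _ = _classical_mds(d)
        sdiff = strict_coords[:, None, :] - strict_coords[None, :, :]
        smax = float(np.abs(np.sqrt((sdiff**2).sum(axis=-1)) - d).max())
        realizable = psd_rank3 and smax <= _STRICT_RESIDUAL
    return EmbeddingResult(
        coordinates=coords,
        realizable=realizable,
        max_residual=max_residual,
        gram_eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# Serialization (versioned JSON text)
# ---------------------------------------------------------------------------


def model_to_text(model: PharmacophoreModel) -> str:
    """Serialize a model to versioned, diffable JSON text."""
    doc = {
        "format": _FORMAT_TAG,
        "version": _FORMAT_VERSION,
        "name": model.name,
        "default_tolerance": model.default_tolerance,
        "points": [
            {
                "label": p.label,
                "accepted_types": sorted(t.value for t in p.accepted_types),
                "tolerance": p.tolerance,
            }
            for p in model.points
        ],
        "target_distances": model.target_distances.tolist(),
    }
    return json.dumps(doc, indent=2) + "\n"


def model_from_text(text: str) -> PharmacophoreModel:
    """Parse and validate a serialized model; errors name the offending field."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelValidationError("top level must be an object")
    if doc.get("format") != _FORMAT_TAG:
        raise ModelValidationError(f"field 'format': expected {_FORMAT_TAG!r}")
    if doc.get("version") != _FORMAT_VERSION:
        raise ModelValidationError(f"field 'version': expected {_FORMAT_VERSION}")
    for key in ("name", "points", "target_distances", "default_tolerance"):
        if key not in doc:
            raise ModelValidationError(f"missing field {key!r}")
    points = []
    for i, p in enumerate(doc["points"]):
        for key in ("label", "accepted_types", "tolerance"):
            if key not in p:
                raise ModelValidationError(f"points[{i}]: missing field {key!r}")
        try:
            types = frozenset(FeatureType(t) for t in p["accepted_types"])
        except ValueError as exc:
            raise ModelValidationError(f"points[{i}].accepted_types: {exc}") from exc
        tol = p["tolerance"]
        if not isinstance(tol, (int, float)) or tol <= 0:
            raise ModelValidationError(f"points[{i}].tolerance: must be a positive number")
        points.append(PharmacophorePoint(p["label"], types, float(tol)))
    d = np.asarray(doc["target_distances"], dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ModelValidationError("field 'target_distances': must be a square matrix")
    if not np.array_equal(d, d.T):
        raise ModelValidationError("field 'target_distances': matrix not symmetric")
    if d[~np.eye(d.shape[0], dtype=bool)].size and np.any(
        d[~np.eye(d.shape[0], dtype=bool)] < 0
    ):
        raise ModelValidationError("field 'target_distances': negative distance")
    try:
        return PharmacophoreModel(
            name=str(doc["name"]),
            points=points,
            target_distances=d,
            default_tolerance=float(doc["default_tolerance"]),
        )
    except ModelValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ModelValidationError(str(exc)) from exc
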