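"""Rule-based protonation adjustment and pharmacophore feature perception.

Perception maps a molecule's atoms and rings onto five feature types —
positive charge, hydrogen-bond donor, hydrogen-bond acceptor, aromatic ring
and hydrophobic group — each anchored at a 3D position taken from one
conformer.  The rules live in an editable tab-separated table of SMARTS
patterns shipped with the package (``data/feature_rules.tsv``), so the
perception scheme can be swapped without touching code.

The default scheme is an *extended* one: donors and acceptors are emitted
both on the heavy atom itself and at a projected interaction-partner site
(~3.2 Å along the direction away from the atom's bonded neighbors, the
canonical hydrogen-bond heavy-atom separation), and aromatic rings are
emitted at the ring centroid plus two π-stacking partner sites along the
ring normal.  Pharmacophore models derived from receptor–ligand complexes
place their points at such interaction sites rather than on ligand atoms,
so matching against them requires both placements.

Protonation follows a fixed physiological-pH (~7.4) convention: aliphatic
amines, amidines and guanidines gain a proton (+1); carboxylic acids and
tetrazoles lose one (-1); pyridine-type ring nitrogens stay neutral.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import Molecule

__all__ = [
    "FeatureType",
    "FeaturePoint",
    "FeatureRule",
    "FeatureRules",
    "default_rules",
    "assign_protonation",
    "perceive_features",
]


class FeatureType(enum.Enum):
    POSITIVE = "POSITIVE"
    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"
    AROMATIC = "AROMATIC"
    HYDROPHOBIC = "HYDROPHOBIC"


@dataclass(frozen=True)
class FeaturePoint:
    """One perceived ligand feature: a type anchored at a 3D position (Å).

    Base single-atom features (POSITIVE, and the on-atom DONOR/ACCEPTOR
    rows) sit exactly on their source atom; ring features sit at the ring
    centroid; projected variants (labels ending in ``-proj``/``-stack``)
    sit at the idealized interaction-partner position instead.
    """

    type: FeatureType
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.source_atoms:
            raise ValueError("FeaturePoint requires at least one source atom")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


# ---------------------------------------------------------------------------
# Rule table
# ---------------------------------------------------------------------------

_PLACEMENTS = ("atom", "projection", "centroid", "normal", "group")
_DEFAULT_LENGTH = {"projection": 3.2, "normal": 4.0}


@dataclass(frozen=True)
class FeatureRule:
    type: FeatureType
    label: str
    placement: str
    length: float
    query: Chem.Mol


@dataclass
class FeatureRules:
    """Compiled perception rules loaded from the tab-separated table."""

    rows: list[FeatureRule]

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureRules":
        rows: list[FeatureRule] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            type_name, label, placement_spec, smarts = parts
            try:
                ftype = FeatureType(type_name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unknown feature type {type_name!r}") from exc
            placement, _, length_s = placement_spec.partition(":")
            if placement not in _PLACEMENTS:
                raise ValueError(f"{path}:{lineno}: unknown placement {placement!r}")
            length = float(length_s) if length_s else _DEFAULT_LENGTH.get(placement, 0.0)
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"{path}:{lineno}: invalid SMARTS {smarts!r}")
            rows.append(FeatureRule(ftype, label, placement, length, query))
        return cls(rows)


_default_rules: FeatureRules | None = None


def default_rules() -> FeatureRules:
    """The rule table shipped with the package, compiled once per process."""
    global _default_rules
    if _default_rules is None:
        with resources.as_file(
            resources.files("phorescreen").joinpath("data/feature_rules.tsv")
        ) as p:
            _default_rules = FeatureRules.from_file(p)
    return _default_rules


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

# Basic nitrogens gaining a proton at pH 7.4.  Aliphatic amines exclude
# amides, sulfonamides, anilines and amidine NH2 (the amidine imine N takes
# the charge instead).  Aromatic (pyridine-type) nitrogens stay neutral.
_AMINE = Chem.MolFromSmarts(
    "[N;X3;+0;!$([N][C,S]=[O,S,N]);!$([N]S(=O)=O);!$([N]a);!$([N][O,N])]"
)
_AMIDINE_N = Chem.MolFromSmarts("[N;X2;+0;!$([N]a)]=[C;X3]!@[N;X3;+0]")
_GUANIDINE_N = Chem.MolFromSmarts("[N;X2;+0]=[C;X3]([N;X3])[N;X3]")
_CARBOXYL_OH = Chem.MolFromSmarts("[CX3](=O)[OX2;H1]")
_TETRAZOLE_NH = Chem.MolFromSmarts("[nH]1nnnc1")


def assign_protonation(mol: Molecule) -> Molecule:
    """Return a copy with formal charges adjusted to a pH ≈ 7.4 convention.

    Aliphatic primary/secondary/tertiary amines, amidines and guanidines are
    protonated (+1); carboxylic acids and tetrazoles are deprotonated (-1);
    everything else is untouched.  Within a polyamine such as piperazine only
    one nitrogen per group is charged (nitrogens within three bonds of an
    already-charged one are skipped).  The operation is idempotent.
    """
    rd = Chem.Mol(mol.rdmol)
    dmat = Chem.GetDistanceMatrix(rd)

    charged: list[int] = [a.GetIdx() for a in rd.GetAtoms() if a.GetFormalCharge() > 0]

    def protonate(idx: int) -> None:
        a = rd.GetAtomWithIdx(idx)
        if a.GetFormalCharge() != 0:
            return
        if any(dmat[idx, j] <= 3 for j in charged):
            return
        a.SetFormalCharge(1)
        a.SetNumExplicitHs(a.GetTotalNumHs() + 1)
        a.SetNoImplicit(True)
        charged.append(idx)

    for pattern in (_GUANIDINE_N, _AMIDINE_N, _AMINE):
        for match in rd.GetSubstructMatches(pattern):
            protonate(match[0])

    for match in rd.GetSubstructMatches(_CARBOXYL_OH):
        o = rd.GetAtomWithIdx(match[2])
        if o.GetFormalCharge() == 0:
            o.SetFormalCharge(-1)
            o.SetNumExplicitHs(0)
            o.SetNoImplicit(True)
    for match in rd.GetSubstructMatches(_TETRAZOLE_NH):
        n = rd.GetAtomWithIdx(match[0])
        if n.GetFormalCharge() == 0:
            n.SetFormalCharge(-1)
            n.SetNumExplicitHs(0)
            n.SetNoImplicit(True)

    Chem.SanitizeMol(rd)
    return Molecule(name=mol.name, rdmol=rd, source=mol.source)


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


def _coords_for(mol: Molecule, coords: np.ndarray | None, conf_id: int) -> np.ndarray:
    if coords is not None:
        arr = np.asarray(coords, dtype=float)
        if arr.shape != (mol.num_atoms, 3):
            raise ValueError(
                f"coords shape {arr.shape} does not cover the {mol.num_atoms} heavy atoms"
            )
        return arr
    if mol.rdmol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol.name!r} has no 3D coordinates")
    conf = mol.rdmol.GetConformer(conf_id)
    return np.asarray(conf.GetPositions(), dtype=float)


def _projection_direction(rd: Chem.Mol, atom: int, xyz: np.ndarray) -> np.ndarray | None:
    """Unit vector from an atom away from the mean of its bonded neighbors."""
    nbrs = [n.GetIdx() for n in rd.GetAtomWithIdx(atom).GetNeighbors()]
    if not nbrs:
        return None
    v = xyz[atom] - xyz[nbrs].mean(axis=0)
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-6 else None


def _ring_normal(xyz_ring: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through the ring atoms."""
    centered = xyz_ring - xyz_ring.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _hydrophobic_groups(rd: Chem.Mol, aliphatic: set[int]) -> list[tuple[int, ...]]:
    """Non-aromatic carbocycles, plus connected aliphatic-C chains of >= 3."""
    groups: list[tuple[int, ...]] = []
    ring_atoms: set[int] = set()
    for ring in rd.GetRingInfo().AtomRings():
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        if all(a.GetAtomicNum() == 6 and not a.GetIsAromatic() for a in atoms):
            groups.append(tuple(sorted(ring)))
            ring_atoms.update(ring)
    chain_atoms = aliphatic - ring_atoms
    seen: set[int] = set()
    for start in sorted(chain_atoms):
        if start in seen:
            continue
        component = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in rd.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in chain_atoms and j not in component:
                    component.add(j)
                    stack.append(j)
        seen |= component
        if len(component) >= 3:
            groups.append(tuple(sorted(component)))
    return groups


def perceive_features(
    mol: Molecule,
    coords: np.ndarray | None = None,
    conf_id: int = 0,
    rules: FeatureRules | None = None,
) -> list[FeaturePoint]:
    """Perceive pharmacophore features on one conformer of ``mol``.

    ``coords`` (n_atoms x 3, Å) overrides the stored conformer ``conf_id``.
    Protonation should already have been assigned; positive charge features
    come from atoms with formal charge > 0.  The returned list is ordered
    deterministically by source atoms, then feature type, then label.
    """
    rules = rules or default_rules()
    xyz = _coords_for(mol, coords, conf_id)
    rd = mol.rdmol

    feats: list[FeaturePoint] = []
    seen: set[tuple] = set()
    aliphatic_filter: set[int] = set()

    def emit(ftype, atoms, pos, label, key_extra=()):
        key = (ftype, atoms, label, *key_extra)
        if key in seen:
            return
        seen.add(key)
        feats.append(FeaturePoint(ftype, tuple(float(c) for c in pos), atoms, label))

    for rule in rules.rows:
        matches = rd.GetSubstructMatches(rule.query, uniquify=True)
        if rule.placement == "group":
            aliphatic_filter.update(m[0] for m in matches)
            continue
        for match in matches:
            if rule.placement == "atom":
                atoms = (match[0],)
                emit(rule.type, atoms, xyz[match[0]], rule.label)
            elif rule.placement == "projection":
                atoms = (match[0],)
                d = _projection_direction(rd, match[0], xyz)
                if d is not None:
                    emit(rule.type, atoms, xyz[match[0]] + rule.length * d, rule.label)
            elif rule.placement == "centroid":
                atoms = tuple(sorted(match))
                emit(rule.type, atoms, xyz[list(atoms)].mean(axis=0), rule.label)
            elif rule.placement == "normal":
                atoms = tuple(sorted(match))
                centroid = xyz[list(atoms)].mean(axis=0)
                normal = _ring_normal(xyz[list(atoms)])
                for sign in (1.0, -1.0):
                    emit(
                        rule.type,
                        atoms,
                        centroid + sign * rule.length * normal,
                        rule.label,
                        key_extra=(sign,),
                    )

    for atoms in _hydrophobic_groups(rd, aliphatic_filter):
        emit(FeatureType.HYDROPHOBIC, atoms, xyz[list(atoms)].mean(axis=0), "hydrophobe")

    feats.sort(key=lambda f: (f.source_atoms, f.type.value, f.label))
    return feats
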