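"""Molecule input/output, molecular-weight filtering, and the bundled fixture library.

Molecules are lightweight wrappers around RDKit molecules carrying a name and
the source record they were parsed from.  The fixture library bundles the
eight approved drugs flagged as prospective non-selective bradykinin-receptor
antagonists together with seeded negative-control decoys that lack any
positive-ionizable group.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "FixtureLibrary",
    "MoleculeParseError",
    "parse_smiles",
    "read_molecules",
    "write_molecules",
    "molecular_weight",
    "weight_filter",
    "fixture_library",
    "HIT_SMILES",
    "DECOY_POOL",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string or structure record cannot be parsed."""


@dataclass
class Molecule:
    """A named small molecule backed by an RDKit ``Mol``.

    Parameters
    ----------
    name : str
        Identifier used throughout reports.
    rdmol : rdkit.Chem.Mol
        Sanitized RDKit molecule (aromaticity perceived, valences checked).
        3D conformers, when present, live on this object.
    source : str
        The SMILES string or file record the molecule came from.
    """

    name: str
    rdmol: Chem.Mol
    source: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- contract checks ----------------------------------------------------
    def validate(self) -> None:
        mol = self.rdmol
        n = mol.GetNumAtoms()
        if n == 0:
            raise ValueError(f"molecule {self.name!r} has no atoms")
        seen: set[tuple[int, int]] = set()
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i == j:
                raise ValueError(f"molecule {self.name!r}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.name!r}: bond atom index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.name!r}: duplicate bond {key}")
            seen.add(key)
            if bond.GetIsAromatic() and not bond.IsInRing():
                raise ValueError(
                    f"molecule {self.name!r}: aromatic bond {key} not in a ring"
                )
        if Descriptors.MolWt(mol) <= 0:
            raise ValueError(f"molecule {self.name!r}: non-positive molecular weight")

    # -- convenience --------------------------------------------------------
    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self.rdmol.GetNumBonds()

    def formal_charges(self) -> list[int]:
        return [a.GetFormalCharge() for a in self.rdmol.GetAtoms()]

    def copy(self) -> "Molecule":
        return Molecule(self.name, Chem.Mol(self.rdmol), self.source)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


def parse_smiles(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Aromaticity is perceived and valences are checked; the molecule carries
    no 3D coordinates.  Raises :class:`MoleculeParseError` naming the
    offending input on failure.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {text!r}")
    return Molecule(name=name or text, rdmol=mol, source=text)


def molecular_weight(mol: Molecule) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    if mol.rdmol.GetNumAtoms() == 0:
        raise ValueError("cannot compute molecular weight of an empty molecule")
    return Descriptors.MolWt(mol.rdmol)


def weight_filter(
    mols: Sequence[Molecule], lo: float = 200.0, hi: float = 600.0
) -> tuple[list[Molecule], list[Molecule]]:
    """Partition molecules into (retained, excluded) by the closed MW window.

    ``retained`` holds molecules with ``lo <= MW <= hi``; input order is
    preserved in both lists.
    """
    if lo >= hi:
        raise ValueError(f"invalid weight window: lo={lo} >= hi={hi}")
    retained: list[Molecule] = []
    excluded: list[Molecule] = []
    for m in mols:
        (retained if lo <= molecular_weight(m) <= hi else excluded).append(m)
    return retained, excluded


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("sdf", "smiles-list")


def read_molecules(path: str | Path, fmt: str = "sdf", lenient: bool = False) -> list[Molecule]:
    """Read molecules from an SDF (V2000) file or a SMILES list file.

    SMILES list files hold one record per line: a SMILES string optionally
    followed by a tab and a name.  With ``lenient=True`` corrupt records are
    logged (with their index) and skipped instead of aborting the read.
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    out: list[Molecule] = []
    if fmt == "sdf":
        if not path.read_text().strip():
            return out
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                msg = f"corrupt SDF record at index {idx} in {path}"
                if lenient:
                    logger.warning(msg)
                    continue
                raise MoleculeParseError(msg)
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{idx}"
            out.append(Molecule(name=name, rdmol=mol, source=f"{path}:{idx}"))
    else:
        for idx, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smi, name = parts[0], (parts[1] if len(parts) > 1 else f"record_{idx}")
            try:
                out.append(parse_smiles(smi, name))
            except MoleculeParseError as exc:
                msg = f"corrupt SMILES record at index {idx} in {path}: {exc}"
                if lenient:
                    logger.warning(msg)
                    continue
                raise MoleculeParseError(msg) from exc
    return out


def write_molecules(mols: Iterable[Molecule], path: str | Path, fmt: str = "sdf") -> None:
    """Write molecules to SDF (V2000) or a SMILES list file.

    Round-tripping preserves atom count, bond count, formal charges and names.
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for m in mols:
            rd = Chem.Mol(m.rdmol)
            rd.SetProp("_Name", m.name)
            writer.write(rd)
        writer.close()
    else:
        lines = [f"{m.to_smiles()}\t{m.name}" for m in mols]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Fixture library
# ---------------------------------------------------------------------------

#: Parent (salt-stripped, free-base) structures of the eight screen hits.
HIT_SMILES: dict[str, str] = {
    "raloxifene": "OC1=CC2=C(C=C1)C(=C(S2)C1=CC=C(O)C=C1)C(=O)C1=CC=C(OCCN2CCCCC2)C=C1",
    "sildenafil": "CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12",
    "cefepime": "CO/N=C(\\C(=O)N[C@@H]1C(=O)N2C(C(=O)[O-])=C(C[N+]3(C)CCCC3)CS[C@H]12)c1csc(N)n1",
    "cefpirome": "CO/N=C(\\C(=O)N[C@@H]1C(=O)N2C(C(=O)[O-])=C(C[n+]3cccc4c3CCC4)CS[C@H]12)c1csc(N)n1",
    "imatinib": "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
    "ponatinib": "Cc1ccc(C(=O)Nc2ccc(CN3CCN(C)CC3)c(C(F)(F)F)c2)cc1C#Cc1cnc2cccnn12",
    "abemaciclib": "CCN1CCN(Cc2ccc(Nc3ncc(F)c(-c4cc(F)c5nc(C)n(C(C)C)c5c4)n3)nc2)CC1",
    "entrectinib": "CN1CCN(CC1)c1ccc(c(c1)NC1CCOCC1)C(=O)Nc1n[nH]c2cc(Cc3cc(F)cc(F)c3)ccc12",
}

#: Hand-curated decoy scaffolds: neutral, mostly rigid, MW within [200, 600],
#: and free of basic amines, amidines and guanidines, so the positive-charge
#: pharmacophore point is unmatchable by construction.
DECOY_POOL: dict[str, str] = {
    "pyrene": "c1cc2ccc3cccc4ccc(c1)c2c34",
    "fluoranthene": "c1ccc2c(c1)-c1cccc3cccc2c13",
    "chrysene": "c1ccc2c(c1)ccc1c2ccc2ccccc21",
    "triphenylene": "c1ccc2c(c1)c1ccccc1c1ccccc21",
    "perylene": "c1cc2cccc3c4cccc5cccc(c(c1)c23)c45",
    "p-terphenyl": "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
    "1,3,5-triphenylbenzene": "c1ccc(-c2cc(-c3ccccc3)cc(-c3ccccc3)c2)cc1",
    "9,10-diphenylanthracene": "c1ccc(-c2c3ccccc3c(-c3ccccc3)c3ccccc23)cc1",
    "triphenylmethane": "C(c1ccccc1)(c1ccccc1)c1ccccc1",
    "tetraphenylmethane": "C(c1ccccc1)(c1ccccc1)(c1ccccc1)c1ccccc1",
    "flavone": "O=c1cc(-c2ccccc2)oc2ccccc12",
    "anthraquinone": "O=C1c2ccccc2C(=O)c2ccccc21",
    "benzil": "O=C(C(=O)c1ccccc1)c1ccccc1",
    "dibenzoylmethane": "O=C(CC(=O)c1ccccc1)c1ccccc1",
    "benzyl-benzoate": "O=C(OCc1ccccc1)c1ccccc1",
    "dibenzyl-ketone": "O=C(Cc1ccccc1)Cc1ccccc1",
    "4,4-dimethoxybiphenyl": "COc1ccc(-c2ccc(OC)cc2)cc1",
    "4-methoxystilbene": "COc1ccc(/C=C/c2ccccc2)cc1",
    "2-phenylbenzothiophene": "c1ccc(-c2cc3ccccc3s2)cc1",
    "4-phenylbenzophenone": "O=C(c1ccccc1)c1ccc(-c2ccccc2)cc1",
    "dimethyl-naphthalenedicarboxylate": "COC(=O)c1ccc2cc(C(=O)OC)ccc2c1",
    "benzanthrone": "O=C1c2ccccc2-c2cccc3cccc1c23",
}


@dataclass
class FixtureLibrary:
    """The bundled screening library: eight named hit drugs plus seeded decoys."""

    hits: list[Molecule]
    decoys: list[Molecule]
    seed: int

    def __post_init__(self) -> None:
        names = sorted(m.name.lower() for m in self.hits)
        if names != sorted(HIT_SMILES):
            raise ValueError(f"fixture hits must be exactly {sorted(HIT_SMILES)}, got {names}")

    @property
    def molecules(self) -> list[Molecule]:
        return list(self.hits) + list(self.decoys)


def fixture_library(n_decoys: int = 0, seed: int = 0) -> FixtureLibrary:
    """Build the fixture library standing in for the screened drug database.

    Hits are the eight named drugs with their canonical parent structures.
    Decoys are drawn deterministically (by ``seed``) from the built-in pool;
    when ``n_decoys`` exceeds the pool size, scaffolds repeat with a numeric
    suffix on the name.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    hits = [parse_smiles(smi, name) for name, smi in HIT_SMILES.items()]
    rng = random.Random(seed)
    pool = list(DECOY_POOL.items())
    decoys: list[Molecule] = []
    round_no = 0
    while len(decoys) < n_decoys:
        order = rng.sample(pool, len(pool))
        for name, smi in order:
            if len(decoys) >= n_decoys:
                break
            label = name if round_no == 0 else f"{name}-{round_no + 1}"
            decoys.append(parse_smiles(smi, label))
        round_no += 1
    return FixtureLibrary(hits=hits, decoys=decoys, seed=seed)
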