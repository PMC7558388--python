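"""Seeded conformer-ensemble generation for flexible molecules.

Ensembles come from stochastic distance-geometry embedding (ETKDG) followed
by force-field minimization, an energy window relative to the ensemble
minimum, and greedy heavy-atom RMSD deduplication.  Generation is fully
deterministic for a fixed (molecule, count, seed, parameters) tuple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Molecule
from .geometry import rigid_rmsd

__all__ = ["ConformerParams", "ConformerEnsemble", "ConformerError", "generate_conformers"]


class ConformerError(RuntimeError):
    """Raised when 3D embedding fails for a molecule."""


@dataclass(frozen=True)
class ConformerParams:
    n_requested: int
    dedup_rmsd: float = 0.5  # Å
    energy_window: float = 20.0  # kcal/mol relative to the ensemble minimum


@dataclass
class ConformerEnsemble:
    """A seeded set of energy-minimized heavy-atom 3D geometries (Å)."""

    molecule: Molecule
    conformers: list[np.ndarray]
    energies: list[float]
    seed: int
    params: ConformerParams

    def __len__(self) -> int:
        return len(self.conformers)

    def validate(self) -> None:
        n = len(self.conformers)
        if not (1 <= n <= self.params.n_requested):
            raise ValueError(f"{self.molecule.name}: conformer count {n} out of contract")
        for k, xyz in enumerate(self.conformers):
            if xyz.shape != (self.molecule.num_atoms, 3):
                raise ValueError(f"{self.molecule.name}: conformer {k} has wrong shape")
        for i in range(n):
            for j in range(i + 1, n):
                if rigid_rmsd(self.conformers[i], self.conformers[j]) < self.params.dedup_rmsd - 1e-9:
                    raise ValueError(
                        f"{self.molecule.name}: conformers {i},{j} below dedup RMSD"
                    )


_CLASH_DISTANCE = 0.5  # Å, minimum allowed non-bonded heavy-atom separation
_MINIMIZE_STEPS = 300  # bounded force-field cleanup per conformer


def _has_clash(rd: Chem.Mol, xyz: np.ndarray) -> bool:
    n = rd.GetNumAtoms()
    bonded = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in rd.GetBonds()
    }
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) not in bonded and dist[i, j] < _CLASH_DISTANCE:
                return True
    return False


def generate_conformers(
    mol: Molecule,
    n: int,
    seed: int,
    dedup: float = 0.5,
    window: float = 20.0,
) -> ConformerEnsemble:
    """Generate a deterministic conformer ensemble for one molecule.

    Candidates are embedded with ETKDG (fixed random seed, single thread),
    minimized with MMFF94 (UFF fallback), pruned to an energy window above
    the ensemble minimum, then greedily deduplicated so every retained pair
    is at least ``dedup`` Å apart in heavy-atom RMSD.
    """
    if n < 1:
        raise ValueError(f"requested conformer count must be >= 1, got {n}")
    params = ConformerParams(n_requested=n, dedup_rmsd=dedup, energy_window=window)

    rdh = Chem.AddHs(Chem.Mol(mol.rdmol))
    etkdg = AllChem.ETKDGv3()
    etkdg.randomSeed = int(seed) & 0x7FFFFFFF
    etkdg.numThreads = 1
    conf_ids = list(AllChem.EmbedMultipleConfs(rdh, numConfs=n, params=etkdg))
    if not conf_ids:
        raise ConformerError(f"3D embedding failed for molecule {mol.name!r}")

    energies: dict[int, float] = {}
    if AllChem.MMFFHasAllMoleculeParams(rdh):
        # Electrostatics are disabled during refinement: in vacuo Coulomb
        # terms collapse protonated species onto their own pi systems and
        # systematically deplete extended geometries from the ensemble.
        # Minimization is deliberately bounded (local cleanup, not full
        # convergence), the usual regime for conformer-database builds.
        props = AllChem.MMFFGetMoleculeProperties(rdh)
        props.SetMMFFEleTerm(False)
        for cid in conf_ids:
            ff = AllChem.MMFFGetMoleculeForceField(rdh, props, confId=cid)
            ff.Minimize(maxIts=_MINIMIZE_STEPS)
            energies[cid] = ff.CalcEnergy()
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(
            rdh, numThreads=1, maxIters=_MINIMIZE_STEPS
        )
        energies = {cid: e for cid, (_, e) in zip(conf_ids, results)}

    heavy = [a.GetIdx() for a in rdh.GetAtoms() if a.GetAtomicNum() > 1]
    candidates: list[tuple[float, int, np.ndarray]] = []
    e_min = min(energies.values())
    for cid in conf_ids:
        if energies[cid] > e_min + window:
            continue
        xyz = np.asarray(rdh.GetConformer(cid).GetPositions(), dtype=float)[heavy]
        if _has_clash(mol.rdmol, xyz):
            continue
        candidates.append((energies[cid], cid, xyz))
    candidates.sort(key=lambda t: (t[0], t[1]))  # energy, then embedding order

    kept: list[np.ndarray] = []
    kept_energies: list[float] = []
    for e, _, xyz in candidates:
        if all(rigid_rmsd(xyz, prev) >= dedup for prev in kept):
            kept.append(xyz)
            kept_energies.append(e)
    if not kept:  # all candidates clashed or collapsed; keep the best one
        e, _, xyz = candidates[0] if candidates else (0.0, -1, None)
        if xyz is None:
            raise ConformerError(f"no usable conformer for molecule {mol.name!r}")
        kept, kept_energies = [xyz], [e]

    ensemble = ConformerEnsemble(
        molecule=mol.copy(), conformers=kept, energies=kept_energies, seed=seed, params=params
    )
    ensemble.validate()
    return ensemble


def write_ensemble_sdf(ensemble: ConformerEnsemble, path: str) -> None:
    """Write an ensemble as a multi-record SDF (one record per conformer)."""
    writer = Chem.SDWriter(str(path))
    rd = Chem.Mol(ensemble.molecule.rdmol)
    rd.RemoveAllConformers()
    for k, xyz in enumerate(ensemble.conformers):
        conf = Chem.Conformer(rd.GetNumAtoms())
        for i, (x, y, z) in enumerate(xyz):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        rd.SetProp("_Name", f"{ensemble.molecule.name}_conf{k}")
        rd.SetDoubleProp("energy_kcal_mol", ensemble.energies[k])
        cid = rd.AddConformer(conf, assignId=True)
        writer.write(rd, confId=cid)
        rd.RemoveAllConformers()
    writer.close()
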