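# phorescreen

Ligand-based pharmacophore perception, matching and virtual screening for
small molecules, built around the bradykinin B1/B2 receptor pharmacophores.

## The scientific problem

The bradykinin receptors B1 and B2 are G-protein-coupled receptors for kinin
peptides. Kinin signalling through them drives vasodilation, vascular
permeability and inflammation, which makes non-selective antagonists —
compounds that block both receptors — attractive therapeutic candidates, and
makes screening *approved* drugs for that profile (drug repurposing) an
attractive shortcut.

Ligand-based pharmacophore models of the two receptors share four feature
points, with a fifth point that discriminates between them:

| point | chemistry                 | B1        | B2                    |
|-------|---------------------------|-----------|-----------------------|
| P1    | positive charge           | shared    | shared                |
| P2    | H-bond donor/acceptor     | shared    | shared                |
| P3    | aromatic ring             | shared    | shared                |
| P4    | H-bond donor/acceptor     | shared    | shared                |
| P5    | receptor-discriminating   | acceptor  | hydrophobic/aromatic  |

Consensus inter-point distances (Å): d(1,2) = 9, d(1,3) = 14, d(1,4) = 10.5,
d(2,3) = 6, d(2,4) = 7, d(3,4) = 7.5; plus receptor-specific P5 rows
(B1: 9.5, 9.3, 9.5, 5.7; B2: 11, 9, 8.8, 8.4 to P1…P4). A ligand that can
present features satisfying P1–P4 simultaneously, in some accessible
conformation, is a candidate **non-selective** antagonist of both receptors.

`phorescreen` implements the full screening engine around these models:

- **chemio** — SMILES/SDF I/O, molecular-weight filtering ([200, 600] g/mol
  by default), and a bundled fixture library of eight approved drugs
  (raloxifene, sildenafil, cefepime, cefpirome, imatinib, ponatinib,
  abemaciclib, entrectinib) plus seeded rigid decoys that lack any
  positive-ionizable group.
- **featperc** — rule-based pH 7.4 protonation and SMARTS-driven feature
  perception, including projected interaction-site features (hydrogen-bond
  partner sites and π-stacking partner sites) alongside on-atom/centroid
  placements; the rule table is an editable TSV shipped with the package.
- **phmodel** — pharmacophore model container, the three built-in bradykinin
  models, classical-MDS distance-geometry embedding with 3D-realizability
  diagnostics, and versioned JSON serialization.
- **confgen** — seeded, deterministic conformer ensembles (ETKDG embedding,
  bounded MMFF cleanup with electrostatics disabled, energy window, RMSD
  deduplication).
- **matcher** — backtracking correspondence search over distance matrices
  with per-pair Å tolerances, a brute-force oracle, and Kabsch superposition
  scoring.
- **screen** — the end-to-end pipeline (filter → protonate → conformers →
  match → selectivity label) with CSV/JSON reports, plus the `phorescreen`
  command-line interface.

Matching operates purely on inter-feature distances, never on embedded model
coordinates: the five-point B1/B2 distance sets are not exactly realizable
in 3D (their centered Gram matrices have a negative eigenvalue), and
distance-space matching absorbs that inconsistency into the pair tolerances
while staying invariant under rigid motions and reflection.

## Worked example

Inspect and embed the consensus model:

```text
$ phorescreen model embed bk_consensus
model bk_consensus (strict): realizable=True max_residual=5.329e-15 Å
gram eigenvalues: [101.5337, 27.4552, 3.1361, -0.0]
  P1: (  -7.949,   -0.475,    0.612)
  P2: (   0.606,   -2.550,   -1.264)
  P3: (   6.020,   -1.329,    1.016)
  P4: (   1.323,    4.354,   -0.364)
```

The four consensus points embed exactly (residual ~1e-15 Å, three positive
Gram eigenvalues); `phorescreen model embed bk_b1` instead reports
`realizable=False` — the fifth point cannot be placed in 3D at its printed
distances, which is why matching works on distances directly.

Match one drug against the consensus model from Python:

```python
from phorescreen import (fixture_library, assign_protonation,
                         generate_conformers, match_molecule, builtin_model)

mol = assign_protonation(fixture_library(0, 3).hits[7])   # entrectinib
ens = generate_conformers(mol, 50, seed=3)
res = match_molecule(ens, builtin_model("bk_consensus"))
```

which prints, via the fields of `res`:

```text
molecule          : entrectinib
matched           : True
best conformer    : 14 of 49
max deviation     : 0.50 A
sum sq deviation  : 0.60 A^2
superposition rmsd: 0.29 A
```

Conformer 14 places a protonated piperazine nitrogen, two donor/acceptor
sites and an aromatic ring within 0.5 Å of every consensus distance —
entrectinib presents the full non-selective pharmacophore. A full screen
(`phorescreen screen run library.smi --seed 42`) repeats this for every
molecule passing the weight filter, against all three models, and labels
each molecule `non_selective_candidate`, `b1_biased`, `b2_biased`,
`consensus_only` (reported as a non-selective candidate), `no_match` or
`filtered_out`; matched molecules are flagged for external docking
follow-up.

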