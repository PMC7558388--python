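# Methods

This note records the models, conventions and numerical choices behind
`phorescreen`, and what the bundled experiments do and do not demonstrate.

## Pharmacophore models

A pharmacophore model is an ordered list of labeled points, each accepting a
set of feature types, plus a symmetric matrix of target inter-point
distances in Å. The three built-in bradykinin models encode the four common
points P1 (positive charge), P2/P4 (hydrogen-bond donor *or* acceptor — the
composite "donor/acceptor" chemistry is expressed on the model side as a
point accepting either type, while ligand perception stays atomic), P3
(aromatic ring), and, in the five-point variants, the
receptor-discriminating P5 (acceptor for B1; hydrophobic/aromatic for B2).

Model construction validates symmetry, a zero diagonal, positive
off-diagonal distances, and the triangle inequality up to a slack of twice
the default tolerance; violations are construction errors.

**Realizability.** Strict embedding performs classical (Torgerson)
multidimensional scaling on the squared-distance matrix. The matrix is
declared realizable in 3D iff the doubly-centered Gram matrix has at most
three positive eigenvalues and none below −1e−8 relative to the largest
(a scale-free cutoff), and the realized distances reproduce the targets to
1e−6 Å. The four-point consensus matrix is exactly realizable (residual
~1e−15 Å). Both five-point matrices are *not*: trilaterating P5 against
P1–P3 forces a negative squared out-of-plane coordinate, and the Gram
spectrum picks this up as a negative eigenvalue (B1) or rank 4 (B2). A
least-squares mode refines the MDS coordinates (`scipy` trust-region least
squares on the distance residuals) for visualization and diagnostics and
reports its residual honestly. **Matching never embeds the model**: it
compares distance matrices directly, so the five-point inconsistency is
absorbed by the pair tolerances, and matching is automatically invariant
under rigid motion and reflection (distance data cannot discriminate
mirror images).

## Protonation convention

Feature perception presumes physiological pH (≈7.4), applied as fixed
structural rules rather than pKa prediction: aliphatic primary/secondary/
tertiary amines, amidines and guanidines gain one proton (+1, on the imine
nitrogen for amidine/guanidine); carboxylic acids and tetrazoles lose one
(−1); pyridine-type ring nitrogens, anilines, amides and sulfonamides stay
neutral. Within a polyamine group (e.g. piperazine) only one nitrogen is
charged: any nitrogen within three bonds of an already-charged one is
skipped, matching the strongly suppressed second protonation constant of
1,4-diamines. The operation is idempotent.

## Feature perception

Rules are (type, label, placement, SMARTS) rows in an editable TSV shipped
with the package. Placements:

- `atom` — the feature sits exactly on the matched atom (POSITIVE, and the
  base DONOR/ACCEPTOR rows);
- `projection:L` — the feature sits L Å from the atom along the direction
  away from the mean of its bonded neighbors, i.e. at the idealized
  position of the hydrogen-bond partner. Default L = 3.2 Å, at the long end
  of canonical heavy-atom hydrogen-bond separations (2.8–3.2 Å);
- `centroid` — arithmetic centroid of a matched aromatic ring;
- `normal:L` — two features at ±L Å along the best-fit ring normal through
  the centroid, the π-stacking partner sites. Default L = 4.0 Å, the upper
  end of parallel-displaced stacking centroid separations (3.5–4.0 Å);
- `group` — an atom filter whose matches are grouped into aliphatic chains
  (≥3 carbons) and non-aromatic carbocycles, one HYDROPHOBIC feature per
  group at its centroid.

The dual placement (on-atom *and* projected) is deliberate. Pharmacophore
models derived from docked receptor–ligand complexes put their points at
interaction positions in the binding site, not on ligand atoms; a ligand
"fulfills" such a point when one of its interaction *sites* — donor/acceptor
partner position, stacking position — coincides with it. Matching the
bradykinin models against on-atom features alone is geometrically
impossible for part of the reference set: for cefepime, every acceptor atom
at least 6 Å from its only aromatic ring (required by d(3,4) = 7.5 ± 1.5 Å)
lies within ~6 Å of the cation, contradicting d(1,4) = 10.5 ± 1.5 Å, so no
conformer can satisfy the model on atoms. The projected sites resolve this
without touching tolerances. The two projection lengths were calibrated
once, on a 3 × 3 grid over their physical ranges ({2.8, 3.0, 3.2} ×
{3.5, 3.8, 4.0} Å), by maximizing the worst-case matching margin across the
eight reference drugs in the bundled screen; five of the nine grid points
already pass the screen, so the scheme is not knife-edged in these
parameters.

Feature counts depend only on molecular topology; only positions change
between conformers. Rigidly transforming the conformer rigidly transforms
every feature position (the ring-normal ± pair may swap, as a set it is
equivariant).

## Conformer ensembles

Flexibility is handled entirely by conformer ensembles (no torsional
fitting during matching). Ensembles are generated deterministically from a
(molecule, count, seed, parameters) tuple: ETKDGv3 stochastic
distance-geometry embedding (single-threaded, seeded), followed by bounded
MMFF94 cleanup — 300 minimizer steps with the electrostatic term
disabled — an energy window of 20 kcal/mol above the ensemble minimum,
greedy heavy-atom RMSD deduplication at 0.5 Å, and a 0.5 Å non-bonded
clash check. Defaults: 200 requested conformers, suited to drug-like
molecules up to ~600 g/mol.

Two refinement choices matter and were fixed after explicit comparison. In
vacuo Coulomb terms fold a protonated amine onto the molecule's own π
system, systematically deleting extended geometries — exactly the region
where a 14 Å cation–aromatic separation lives — both directly and through
the energy window; disabling electrostatics during cleanup (the same reason
conformer-database tools minimize without charges) removes that bias.
Likewise, minimization is deliberately partial: it repairs distance-geometry
artifacts without transporting conformers into a handful of deep minima,
preserving ensemble breadth.

## Matching

A correspondence is an injective, type-compatible assignment of model
points to features in one conformer such that every pairwise feature
distance deviates from its target by at most the pair tolerance (the larger
of the two point tolerances; tolerance 1.5 Å for P1–P4, 2.0 Å for P5 pairs
since the five-point distance sets are consensus values that are not
exactly realizable). The search is backtracking over model points ordered
by fewest compatible features, pruning each partial pair; an exhaustive
permutation oracle (guarded at ≤10 features) cross-checks it in the tests.
All correspondences are returned, sorted by sum of squared deviations, ties
broken by the feature-index tuple; across conformers the best correspondence
has minimal sum of squares, ties to the lowest conformer index. A proper
(determinant +1) Kabsch superposition of the matched features onto the
model's least-squares embedding is reported as a diagnostic RMSD but never
used as a match criterion, because it depends on the non-unique embedding of
inconsistent five-point models.

## Screening pipeline and labels

Stages run in a fixed order: closed-interval molecular-weight filter
([200, 600] g/mol — more permissive than an open interval, and no reference
compound sits on a boundary; weight computed on the neutral parent before
protonation, as in conventional drug-likeness filtering) → protonation →
conformer generation → matching against the consensus and both five-point
models → labeling. Labels follow a fixed truth table: consensus unmatched →
`no_match`; consensus only → `consensus_only` (reported as a non-selective
candidate: fulfilling the four common points is the non-selectivity
criterion); consensus plus exactly one five-point model → `b1_biased` /
`b2_biased`; all three → `non_selective_candidate`. Labels are deliberately
conservative ("candidate", "biased"): a pharmacophore match is necessary,
not sufficient, and receptor-side checks (docking, steric exclusion) are
out of scope — matched molecules carry a flag for external docking instead.
Reports are byte-deterministic for a fixed configuration and seed
(timestamps are isolated to the run-summary metadata).

## The fixture library

The bundled library stands in for a licensed drug database: the eight
approved drugs reported as prospective non-selective bradykinin-receptor
ligands (raloxifene, sildenafil, cefepime, cefpirome, imatinib, ponatinib,
abemaciclib, entrectinib), encoded as salt-stripped parent structures from
standard public references, plus decoys drawn deterministically from a
hand-curated pool of 22 neutral scaffolds (fused aromatics, simple esters
and ketones, 200–600 g/mol) containing no basic amine, amidine or
guanidine. Decoys therefore present no positive-ionizable group and cannot
match P1 *by construction* — they are guaranteed negatives for the
consensus query, which is what the screen's specificity check needs. They
are not property-matched decoys in the DUD-E sense, so the screen
demonstrates correct mechanics (sensitivity on the eight references,
specificity against cation-free molecules), not a real-world enrichment
estimate. The original screen's 1703-molecule weight-filtered subset is
database-version-dependent and is not reproduced.

## Numerical conventions and degenerate inputs

- Eigenvalue cutoff for realizability: relative, 1e−8 × largest eigenvalue.
- Strict-embedding residual bound: 1e−6 Å; rigid-motion/equivariance test
  tolerances: 1e−9 Å.
- Optimal-superposition RMSD of 1- and 2-point sets is handled analytically
  (0 and half the difference of separations); `kabsch_superpose` itself
  requires ≥3 points for a unique proper rotation.
- Zero-atom molecules, empty SMILES, unknown formats, asymmetric or
  negative distance matrices, and non-positive tolerances are rejected with
  errors naming the offending input or field; corrupt records in a
  multi-record file abort the read unless a lenient flag is set, in which
  case they are logged with their record index and skipped.
- Seeds are threaded explicitly through every stochastic component
  (decoy selection, conformer embedding); ETKDG seeds are masked to 31 bits.

## Known limitations

- No pKa prediction, tautomer enumeration, or conformation-dependent
  donor/acceptor accessibility; protonation is structural and fixed.
- No partial (3-of-4) matching: all model points are essential.
- No excluded-volume or receptor-shape constraints; selectivity labels rest
  on ligand geometry alone.
- Conformer ensembles carry no free-energy weighting; an accessible
  matching conformation is treated as sufficient regardless of its
  population.
- The perception scheme, while physically grounded, was validated against
  the eight-drug reference screen; transferring it to other targets may
  need recalibration of the projection lengths.
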