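# Methods

This note documents the models, conventions and numerical choices behind
`overlaybench`, and what the synthetic test substrate does and does not
establish about behaviour on real crystallographic data.

## Structure ingestion

PDB entries are parsed with gemmi; only the first model is read, and
alternate conformers other than altLoc 'A'/blank are dropped with a
logged warning. Waters (HOH/DOD) are removed before ligand-candidate
listing so that "no ligand" entries are counted meaningfully. Resolution
comes from `REMARK 2` and the release date from the `HEADER` (or
`REVDAT 1`) record; an entry without a parseable resolution is retained
at parse time and later fails the resolution gate — unknown resolution
cannot certify quality.

Construction-time exclusions, assigned before any filtering:

* `metal_ion` — a single non-carbon heavy atom of a metallic element
  (explicit list Na…Hg plus anything the periodic-table module flags
  metallic);
* `covalent` — any ligand heavy atom within 1.9 Å (configurable) of a
  protein heavy atom; a distance gate is the standard reconstruction of
  covalent-adduct detection;
* `polymer` — HETATM groups linked to other HETATM groups below the same
  cutoff (sugar chains, covalent oligomers);
* `unparseable` — bond-order perception failure.

## Ligand perception and descriptors

Bond orders and protonation are perceived from element identities and 3D
coordinates with RDKit's connectivity/valence assignment, which requires
hydrogens to be present. The synthetic fixtures therefore always emit
explicit hydrogens. Real deposited structures usually lack ligand
hydrogens; handling them would need a valence-inference step that this
package does not implement — a known limitation when pointing the
pipeline at raw PDB files.

Descriptor conventions (fixed here because toolkit defaults differ):

* **Rotatable bonds** — acyclic single bonds, excluding amide C–N bonds,
  bonds involving a nitrile-group atom, and bonds where either end is a
  terminal heavy atom. This is deliberately *not* RDKit's default SMARTS.
* **HBD** — one count per hydrogen on N or O.
* **HBA** — N and O atoms, excluding pyrrole-type N–H nitrogens and amide
  nitrogens.
* **SlogP** — Wildman–Crippen atomic contributions (RDKit `MolLogP`).
* **SMILES** — canonical isomeric SMILES; uniqueness (duplicate removal,
  ensemble deduplication) is therefore stereochemistry-aware.

## Activity ledger and ligand efficiency

IC50, EC50, Ki and Kd records are pooled; values are converted to molar
and normalized as p(value) = −log₁₀(value). Records are never compared
across assay types — they serve only to bound the ligand's efficiency
from below. "Lowest value" is read as the *minimum p* (the weakest
measurement), which realizes the minimum estimated LE; since the phrase
could also mean the lowest molar concentration (which would give the
*highest* LE), the other reading is available via
`le_value_selection="min_molar"`. The minimum is taken over the multiset
of records, so duplicated records are harmless. LE = 1.37 · p / hac.

## Filter cascade

The ten gates run in a fixed order and every discarded ligand is
attributed to its first failing step, which makes the per-step report
conserve counts exactly (remaining_before − discarded = remaining_after).
Default thresholds: resolution ≤ 2.5 Å; EDIA_m > 0.8 (strict — the source
recommendation retains scores *greater than* 0.8; a ligand without a
score fails rather than bypasses the gate); MW ≤ 975 g·mol⁻¹; rotatable
bonds ≤ 10; allowed elements C, O, N, S, P, Cl, F, Br, I, B; heavy atoms
≥ 10; LE > 0.3 (strict); buriedness ≥ 0.5.

**Buriedness** is the fraction of the ligand's solvent-accessible surface
area lost in the complex: 1 − SASA(ligand in complex)/SASA(ligand alone),
Shrake–Rupley with probe 1.4 Å and element vdW radii, clamped to [0, 1].
The original operator is an unpublished in-house application; the SASA
burial fraction is the standard surface-based reading, and a
neighbor-count alternative (fraction of ligand heavy atoms with ≥ 2
protein heavy atoms within 4.5 Å) is available behind
`buriedness_method="neighbor_count"`. An independent Monte-Carlo surface
oracle anchors the SASA implementation in the tests.

## Ensemble generation

The binding site of a ligand is every residue with at least one atom
(hydrogens count) within 6.5 Å (configurable) of any ligand atom. The
site's **signature** is the per-chain concatenation of one-letter codes
in residue order; chains are ordered canonically by (selected-run length
descending, sequence string). Non-standard residues map to 'X' and must
match as 'X'. Two sites are identical when their per-chain strings agree
as multisets; with the canonical order, equal strings pair positionally,
which fixes one valid chain bijection deterministically. This
exact-string matching deliberately replaces fault-tolerant site search:
no gaps, no mutations.

Superposition uses the Kabsch algorithm (SVD with determinant
correction, proper rotation) over the backbone N/CA/C/O atoms of the 1:1
residue pairing, restricted to residue pairs where both residues are
backbone-complete; a hit with fewer than three usable residues is
skipped with a log entry. The ensemble frame is the query structure's
crystal frame. Degenerate inputs (< 3 points, collinear sets) raise
rather than returning an ill-defined transform.

Deduplication keeps, per canonical SMILES, the member with the lowest
backbone RMSD (ties: lexicographically smallest ligand key, logged);
ensembles reduced below two members are removed.

## Clustering

Two ensembles intersect when they share a (entry, ligand) complex.
Ensembles are processed by size descending, then name ascending; an
ensemble intersecting several existing clusters merges them. Full
merging makes the result equal to the connected components of the
shared-complex graph — independent of processing order — and guarantees
that representatives of different clusters never share a complex. A
strict first-match variant (no merging) is exposed via
`cluster_merge=false` for comparison; it does not guarantee that
property. The representative is the ensemble whose search ligand has the
highest heavy atom count; ties fall back to name order (logged).

## Pair subsets

Volumes are hard-sphere grid volumes over heavy atoms with Bondi radii
(default spacing 0.4 Å, margin twice the largest radius). Hydrogens are
ignored: crystal ligands often lack them and volume scoring conventions
do likewise. With t = 1, q = 0 the Shape Tversky Index is the covered
fraction of the template volume; the grid is validated against the
analytic sphere–sphere lens volume (≤ 2 % relative error at 0.25 Å
spacing) and a Monte-Carlo oracle, and halving the spacing moves the
index by < 0.01 on the fixture suite. Bins are half-open
([0.8, 0.9) → `subset_80`); an index of exactly 1.0 joins `subset_90`,
otherwise identical molecules would be unbinned. Pairs are generated
from representative ensembles only.

## Diversity analytics

* **Bemis–Murcko scaffold** — ring systems plus linkers after iterative
  pruning of acyclic substituents (RDKit framework); acyclic molecules
  yield the empty scaffold, counted as its own class.
* **Scaffold AUC** — area under the recovery curve: scaffolds sorted by
  frequency descending, points (i/N_scaffolds, cumulative molecule
  fraction) including the origin, trapezoid rule. 0.5 = every molecule
  its own scaffold; → 1 = concentration on few scaffolds. A single
  scaffold class degenerates to the diagonal (0.5) and is flagged with a
  warning rather than special-cased. Note that the AUC is not monotone
  under merging arbitrary scaffold classes (merging rescales the
  scaffold axis); the clean monotonicity — concentrating counts at a
  fixed number of scaffolds raises the AUC — is what the property tests
  assert.
* **Median MACCS Tanimoto** — median over all unordered distinct pairs of
  166-key fingerprints; absent below two molecules. Together with the
  scaffold AUC it forms the consensus-diversity coordinates; the output
  table uses named columns so no axis convention is imposed.
* **Ensemble HAC spread** — mean and *sample* (n − 1) standard deviation
  of member heavy atom counts. The estimator is pinned by the two-ligand
  reference case {18, 43} → 17.68 (a population estimator would give
  12.5).
* **Release growth** — each pair is dated max(year of entry A, year of
  entry B), the first moment both structures were public; pairs with a
  missing date are excluded with a log line.

## Synthetic fixtures

The generator emits toy complexes: backbone-only "peptide cages" on a
shell around embedded RDKit conformers. Cage positions come from a fixed
raster, constrained to be ≥ 3 Å from every ligand atom (so the covalent
gate never fires; each residue's tangent frame is rotated to maximize
clearance, and residues that cannot clear are dropped) and ≤ 6.5 Å of
*every* ligand pose of a pocket family (so each family ligand selects the
entire cage and signatures match exactly). Sequences are random but
fixed per family.

The ensemble scenario engineers each pipeline branch:

* a seven-structure family whose backbone copies are displaced along two
  rigid-motion-free deformation fields — backbone RMSDs between members
  are then distances in a 2-D plane (0.06 Å per unit), which controls
  every SMILES-deduplication choice and creates two seed clusters that a
  late-processed bridging ensemble merges (the multi-intersection path);
* a coincident family (naphthalene placed on the matched substructure
  coordinates inside phenanthrene) for near-complete coverage;
* a stacked family (two ligands 3.5 Å apart in one fully shared cage)
  whose pairs have exactly zero overlap — ligands in different parts of
  the same pocket;
* a singleton family whose ensemble is removed.

Ground-truth pair labels come from a generator-side Monte-Carlo Shape
Tversky oracle, independent of the pipeline's grid; the generator
refuses engineered placements within 0.03 of a bin edge, so oracle and
grid always agree on the label. Scenario *content* is a pure function of
fixed internal seeds; the user seed only randomizes each structure's
rigid placement in space, so the documented expected outcomes hold for
any seed while files still differ byte-wise between seeds (and are
byte-identical for equal seeds).

What the fixtures do not emulate: real fold geometry, electron density,
partial occupancies, alternate conformers, missing residues, unparseable
chemistry at scale, and realistic affinity distributions (values are
placed relative to the thresholds). Passing the suite therefore shows
the *operators* are correct under their stated definitions, not that the
selection reproduces any particular census of the PDB — absolute counts
of the full-scale dataset depend on the source snapshot and activity
databases and are out of scope.

## Problem sizes

The shipped scenarios use 11–12 structures of 30–90 residues with 9–70
heavy-atom ligands; the acceptance script runs the full pipeline on both
scenarios plus 100 random superposition and 100 random clustering
instances, and completes in well under a minute on one CPU. These sizes
were chosen so every branch of the method is exercised with margins
(bin-edge distance, RMSD-ordering gaps) that make the expected outcomes
robust, not to benchmark throughput.
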