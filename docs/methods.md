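# Methods

## The system and the question

Laminin polymer nodes are trimeric assemblies of the N-terminal LN domains
(jelly-roll β-sandwiches of 7–8 antiparallel strands) of one α, one β and
one γ short arm. Pathogenic missense mutations in LN domains abolish
polymerization without necessarily destroying the subunit fold, which makes
their *local structural context* — rather than a global stability estimate —
the informative quantity. The pipeline therefore computes, for each
catalogued mutation on a wild-type node model, a per-residue feature profile
and maps it to one of four mechanistic classes.

## Feature detectors

All detectors are geometric; no energies or statistical potentials are used.

**Interfaces.** A residue is an interface residue with respect to a partner
chain when any of its heavy atoms lies within the contact cutoff
(default 5.0 Å) of any heavy atom of that chain. The source material names
interface residues by visual inspection and states no cutoff; 5 Å
heavy-atom contact is the package's operationalization and is configurable
(`RunConfig.interface_contact`). The definition is reciprocal by
construction: chain A has an interface residue toward B iff B has one
toward A.

**Hydrogen bonds.** Donor and acceptor atoms come from a packaged chemistry
table (backbone N donates except in proline; backbone O accepts; polar side
chain atoms per residue type; S donors/acceptors included). A candidate pair
within 3.5 Å heavy-atom distance is accepted if

* a hydrogen bound to the donor exists (≤ 1.3 Å): maximal D–H···A angle
  ≥ 120°; else
* the donor's antecedent heavy atom exists: antecedent–D···A angle ≥ 90°;
  else (minimal scaffolds without side chains) distance alone decides.

Pairs below 2.4 Å are treated as covalent/clash geometry and skipped, as are
donor/acceptor within one residue. Predicted-model deposits are usually
relaxed with hydrogens present, so the angular criterion tightens exactly on
the models where hydrogens are trustworthy.

**Disulfides.** CYS SG pairs within 2.5 Å, matched greedily by increasing
distance so each cysteine joins at most one bridge. Cysteines lacking an SG
atom are skipped rather than fatal (reduced or partially modelled side
chains occur in real files).

**Solvent accessibility.** Shrake–Rupley with a deterministic golden-section
spiral of 960 points per atom, probe 1.4 Å, van der Waals radii from a
packaged element table (C 1.70, N 1.55, O 1.52, S 1.80 Å, default 1.70 Å
with a warning pathway for unknown elements). Hydrogens are excluded from
both the surface and the occluders, matching the heavy-atom maximal-area
reference. Relative accessibility divides the per-residue sum by Tien-style
theoretical maxima; values slightly above 1 occur for extended chains and
are kept (flagged above 1.2). The sphere-point set is fixed in the world
frame, so SASA is exactly translation-invariant while rotations perturb
areas only at quadrature resolution (≈ 1% at 960 points); the tests assert
exactly that, rather than a false bitwise rotation invariance.

**Sequons.** N-X-[S/T] with X ≠ P, scanned over consecutively numbered
residues so chain breaks and insertion-code regions never produce spurious
hits. Sequon proximity is the minimal heavy-atom distance from a residue to
any sequon asparagine of the same chain (0 for the Asn itself, ∞ when the
chain has no sequon).

**Hydrophobic cores.** Residues of type {A, V, L, I, M, F, W, Y, C} with
relative accessibility below 0.10.

## The four-class rules

Precedence 3 → 1 → 2 → 4, evaluated on the wild-type node:

| class | rule |
|---|---|
| 3 disulfide | wild-type residue is CYS engaged in a detected disulfide |
| 1 interface | interface membership OR an inter-chain hydrogen bond |
| 2 glycosylation-adjacent | sequon distance ≤ 10 Å AND rSASA ≥ 0.2 |
| 4 hydrophobic core | buried apolar residue |
| 0 unclassified | none of the above; diagnostics attached |

Disulfide membership is unambiguous, hence first. Interface loss is the
primary polymerization-failure mechanism and outranks the surface and core
descriptions. The class-2 rule renders "adjacent to an invariant
glycosylation site on the back face" as proximity plus exposure; both
thresholds are configurable, and any assignment whose deciding quantity
falls within 10% of its threshold is flagged as borderline. Classification
always runs on wild-type context; mutant models serve only the
hydrogen-bond difference report (`hbond_diff`), which keys bonds on
(donor residue, acceptor residue) so an atom-level rearrangement within the
same residue pair does not register as loss plus gain. The transcribed
literature class labels live exclusively in the evaluation harness
(`CatalogEntry.paper_class`); the classifier interface cannot see them.

## Superposition metrics

The optimal least-squares rotation is the Kabsch SVD solution with the
determinant sign corrected, so a reflection is never returned (asserted per
call together with orthonormality). Fewer than 3 points or a collinear fit
set raises a geometry error. Three RMSD flavours: all paired heavy atoms;
backbone N/CA/C/O; and pruned. Model-level superposition pairs residues by
author numbering or by global sequence alignment and intersects atom names
within each residue pair.

**Pruning protocol.** Cutoff 2.0 Å, at most 20 iterations. Each iteration
re-fits on the retained pairs and then re-evaluates *all* pairs under the
new transform, retaining those within the cutoff, until the retained set is
stable. This fixed-point formulation lets a pair discarded under an early,
outlier-skewed fit re-enter once the fit settles — without it, a heavily
displaced minority can drag the initial fit far enough that well-matched
pairs are lost permanently. The price is that the pruned RMSD is not
strictly monotone across iterations (a reclaimed borderline pair can raise
it marginally); the tests assert the fixed-point properties instead. Whether
published "pruned atom pairs" figures use a 2.0 Å criterion is not stated
anywhere authoritative; the default is documented as an assumption and
configurable.

## Sequence comparison

Pairwise affine-gap global alignment (Needleman–Wunsch–Gotoh) through
Biopython's `PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5 —
conventional defaults, not values prescribed by the source material. The
ambiguity code X scores 0 against everything. Percent identity uses the
aligned-columns denominator (identical columns / columns with at least one
residue); the alternative shorter-sequence denominator is available via the
alignment result's fields. Identity matrices align each unordered pair once
in label-sorted order, making the matrix symmetric and record-order
invariant by construction. Conservation mapping scores each chain position
as the frequency of the most common residue in its alignment column across
the supplied homologs (gap = mismatch).

## Synthetic fixtures

The generator builds what the detectors need to be tested against, at toy
scale, from ideal backbone geometry (bond lengths/angles from standard
peptide values; φ/ψ −57°/−47° for helix, −139°/135° for strand; ω trans;
NeRF chain extension):

* two parallel strands with a 4-residue window of one chain brought to a
  target minimum heavy-atom distance (4.5 Å) of the other by bisection — the
  planted interface;
* a tyrosine OH placed 2.9 Å from a window backbone O, with a deterministic
  direction search keeping it > 3.6 Å from every other partner-chain atom so
  the planted bond is the *only* inter-chain hydrogen bond;
* two cysteines with SG atoms exactly 2.05 Å apart;
* an N-G-T sequon with a serine probe two residues upstream;
* four leucines on a tetrahedron buried under a 48-glycine shell (radius
  6.2 Å), which the 1.4 Å probe cannot penetrate;
* a third, distant chain so the node is a proper α/β/γ trimer.

Default plants keep ≥ 0.4 Å margin to every detection threshold, so the
0.05 Å coordinate jitter used to diversify fixtures across seeds never flips
a label. Every fixture is audited before emission: detectors re-run on the
built model must reproduce the planted truth exactly, and the four planted
mutation sites must classify into their intended classes. Truth labels are
written to a sidecar JSON, never into coordinate files. All randomness flows
from the single recorded seed; equal specs give bitwise-equal fixtures.

What the fixtures deliberately are **not**: chemically plausible proteins.
There are no side-chain rotamers beyond CB, covalent continuity is broken
where the interface window is shifted, and the buried cluster is a
constructed cage rather than a jelly-roll core. Passing the planted-recovery
suite therefore shows that the detectors implement their geometric
definitions exactly; it does not show that the thresholds are optimal for
real structures. That calibration question is what the deposited-structure
benchmarks address — they require the published coordinate files
(`scripts/fetch_structures.py`) and compare the disulfide census, the
predicted-vs-experimental RMSDs and the catalog class partition against
published values.

## Numerical and procedural choices

* Residue numbering follows the author numbering of the source file;
  per-chain offsets are available in configuration to reconcile isoform
  numbering.
* Alternate locations collapse to the highest-occupancy conformer, ties
  broken alphabetically, for deterministic downstream geometry.
* Waters are dropped at parse time; other heteroatoms are kept and flagged,
  and excluded from the donor/acceptor chemistry.
* pLDDT is read from the B-factor column only for models marked computed;
  experimental models are refused with an explanatory error.
* Chain-to-subunit tagging accepts an explicit mapping, a reference FASTA
  (best identity ≥ 60%), or — for files loaded from a model directory — a
  file-stem convention (`alpha2beta1gamma1.pdb` tags chains in file order).
* LN vs LN+LE1 residue ranges are configuration (`RunConfig.regions`),
  defaulting to whatever span the reference structure provides, since exact
  domain boundaries are not universally fixed.
* Problem sizes in the shipped analyses — 50 fixtures for recovery metrics,
  1000 atoms for the noise-expectation check, 5 four-atom toys for the
  rotation-grid oracle — were chosen to make the statistical checks sharp
  (sampling error well below the asserted tolerances) while keeping each
  driver in the tens of seconds on one core.

## Known limitations

* The classifier measures wild-type context only; it cannot see misfolding,
  kinetic, or glycosylation-machinery effects, and carries any ΔΔG values
  purely as annotations.
* Class-2 "adjacency" collapses a biological statement (interference with
  glycosylation) into a distance-and-exposure rule; borderline calls are
  flagged, not resolved.
* SASA rotation invariance holds only to quadrature resolution (see above).
* The interface sub-assignment (α–β vs α–γ vs β–γ) is reported as evidence
  metadata, not as a class.
* Pairwise identity percentages depend on alignment engine and exact domain
  boundaries; range-level agreement, not cell-exact reproduction, is the
  supported comparison for published identity matrices.
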