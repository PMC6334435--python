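# Methods

This note documents the models, conventions and numerical choices behind
`tklscan`, and what the synthetic test conditions do and do not establish
about real data.

## Data model and addressing

Structures are parsed (via gemmi) into a minimal hierarchy — chains of
author-numbered residues of atoms, plus a flat set of hetero residues
(ligands, metal ions, waters). Author numbering with insertion codes is the
canonical addressing scheme everywhere, because that is how active-site
residues are cited in the literature (H77, H110, E366); sequential indices
never cross a module boundary. Alternate locations are resolved at read time
to the highest-occupancy conformer, ties broken toward altloc `A`.
Writing emits fixed-width PDB records directly; round-trip tests hold
coordinates to the 10⁻³ Å field width, and a second, independent PDB
implementation is used in the tests to confirm the files are well formed.
Waters are retained as flagged ligands but excluded from interaction
detection by default; a covalent multi-part adduct is declared as one rigid
ligand group through a het-code selection.

## Alignment statistics

A column is *identical* when both rows carry the same letter, *conserved*
when the letters are identical or share a similarity group. The default
scheme — `{ILMVFWYC} {KRH} {DE} {NQ} {ST} {AG} {P}` — follows the grouping
conventions of alignment-rendering tools; because no single numeric
definition of "conserved" is standard, the scheme is configuration, not a
constant, and reproductions of published percentages are tolerance checks
(±2 points) rather than exact targets. Percentages default to the ungapped
reference length as denominator (statistics are quoted "relative to" a
reference); the symmetric aligned-columns denominator is available. Region
intervals are closed and expressed in reference numbering, where reference
numbering is the 1-based ungapped position (identical to UniProt numbering
for a full-length row). Deletion blocks are maximal runs of
reference-residue-versus-gap columns; columns gapped in both rows do not
interrupt a run.

## Superposition and ligand transplantation

The rigid fit is the closed-form Kabsch solution (SVD of the centred
covariance, determinant-corrected so a reflection is never returned) over
Cα pairs matched through the alignment map — one pair per column where both
sequences resolve to a residue with a Cα. Fewer than four pairs, or
collinear/coincident sets, are errors. The iterative variant re-fits after
discarding pairs deviating more than a cutoff (default 2.0 Å, at most 20
rounds), emulating the default behaviour of interactive superposition
tools; since published RMSDs rarely state whether pruning was applied, both
`rmsd_all` and `rmsd_pruned` are always reported. Ligand transplantation
applies the fitted template→query transform to the selected ligand group;
rigidity guarantees intra-ligand distances to well below 10⁻⁶ Å, which the
tests assert via the full distance matrix.

## Interaction detection

Hydrogen bonds are detected from heavy atoms only by default, since crystal
structures and homology models rarely carry hydrogens. The criteria are the
package's realization of the classical geometric distance/angle rules:

| parameter | default | meaning |
|---|---|---|
| `d_DA_max` | 3.5 Å | donor–acceptor distance ceiling |
| `donor_angle_min` | 90° | minimum angle at the donor between every bonded heavy neighbour and the acceptor |
| `acceptor_angle_min` | 90° | same screen at the acceptor |
| `d_HA_max`, `angle_DHA_min` | 2.5 Å, 120° | used only when hydrogens are present and heavy-atom mode is off |
| `metal_coord_max` | 2.6 Å | metal coordination sphere |
| `contact_max` | 4.5 Å | hydrophobic/probe contact radius |

Pairs closer than 1.5 Å are treated as covalent, not hydrogen-bonded.
Covalent neighbours are inferred from inter-atomic distances against scaled
covalent-radius sums (factor 1.3), including the inter-residue backbone
C–N link. Loosening any single threshold can only add bonds (monotonicity,
property-tested). Donor/acceptor typing is a per-residue table whose group
labels are the field's vocabulary (ε-NH₂, τ-NH, backbone amide, hydroxyl,
carboxylate, amide-NH₂, thioether-S, ...); histidine ring nitrogens are
typed donor-or-acceptor because protonation is unknown in model files, with
the τ label on NE2 by atom identity, and the thiazole sulphur is typed as a
weak acceptor (config-exposed) so that τ-NH⋯S bonds are observable. Group
counts collapse multiple bonds from one chemical group — two phosphate
oxygens bonded by the same lysine ε-NH₂ count once. Pairs whose two
partners both coordinate the same metal are reported as metal-mediated, not
as hydrogen bonds. Ligand atoms are typed and partitioned into regions
(diphosphate, aminopyrimidine, thiazole, methylene bridge, xylulose) by an
editable per-het-code table, because adduct atom nomenclature varies between
file sources. The hydrophobic nodule is the residue ranked first by minimum
side-chain distance to the probe selection (default: the methylene-bridge
atoms) among residues with Kyte–Doolittle value ≥ a floor (default 0); the
published 20-residue hydropathy table is shipped as the data source.
Aromatic stacking is not scored geometrically; ring packing reaches the
report through the hydrophobic-contact channel.

## Equivalence mapping and interaction fate

Each template site residue is mapped through its alignment column to the
query; the relation is `identical`/`similar`/`different` by letter and
similarity group, or `absent` when the column is gapped (the fate of TKT
H77 and H110 against TKTL1). With both complexes in one frame, a template
interaction is *conserved* if the equivalent query residue touches the same
ligand region, *substituted* if a different query residue interacting with
that region sits within a spatial tolerance (default 3.0 Å, the package's
quantification of "at a similar position") of the template partner, else
*lost*; query interactions with no template counterpart are *gained*.
Catalytic annotations on the shipped template site list (H77, H110, E366,
Q428) are metadata only and never enter the classification. The shipped
list includes G123 for the ring-interaction glycine; the literature also
cites G125 for the same contact, and the config notes the discrepancy.

## Validation

φ is C(i−1)–N–Cα–C and ψ is N–Cα–C–N(i+1), signed per IUPAC and reported in
(−180°, 180°]; a dual, independently derived projection formula cross-checks
the implementation to 10⁻⁹ degrees. Chain breaks (Cα–Cα > 4.5 Å or missing
backbone atoms) leave angles undefined. Residues are classed as
general/glycine/proline/pre-proline and classified against editable region
polygons with ±360° wrapping and half-degree edge slack. The shipped
polygons are deliberately coarse boxes: external validation servers use
data-derived contours whose levels differ, so comparisons to their printed
fractions are tolerance checks (≥98% allowed), never bit-exact targets.
3D-1D environment profiling and rotamer analysis require external
statistical tables and are intentionally not computed; every summary lists
them under `not_computed` so their absence is explicit in the reports.

## Synthetic study conditions

The generator builds a two-chain scaffold: an ideal-geometry helical
backbone (NeRF internal-coordinate placement; bond lengths/angles from
standard peptide values, ω = 180°) with tree-placed side chains — correct
atom names, plausible bond distances and connectivity, but no rotamer or
ring-closure realism and no energy minimisation, which is sufficient for
geometric operators. Chain B is chain A rotated 180° about the cleft axis,
so an axis-aligned pseudo-ligand sees both chains with identical distance
sets (the symmetric-cleft fixture). Planted hydrogen bonds place a ligand
atom along the donor's free-valence direction at a stated distance; planted
distances in the headline run sit at typical strong-bond lengths
(2.7–3.0 Å) so they survive the modelled coordinate noise with margin under
the 3.5 Å cutoff. The generator validates satisfiability (no clash below
1.5 Å, ligand-atom separation, guard distances that keep unplanted ligand
atoms out of hydrogen-bonding range) and raises rather than emitting an
unverifiable fixture; it is a pure function of its spec and seed, and
byte-identical outputs for identical specs are asserted.

The headline acceptance run mirrors the study conditions the pipeline is
built around: 120-residue chains with a planted 38-residue deletion spanning
reference positions 76–113 (G to P), two-row alignments constructed with
exactly 60/81 and 64/92 identical/conserved columns per 100, five distinct
protein groups hydrogen-bonded to the diphosphate side, one τ-NH⋯thiazole-S
bond, a leucine planted against the methylene bridge as the hydrophobic
nodule, and Gaussian coordinate noise of σ = 0.23 Å per coordinate — sized
so the Cα RMSD (≈ σ√3) lands near the ~0.4 Å template/model deviation the
method operates at.

What passing these conditions shows: the operators recover planted truths
exactly at zero noise and stably at the modelled noise level. What they do
not show: performance on real crystallographic pathologies (alternate
conformations beyond simple altlocs, chain gaps, non-standard residues,
adduct naming variants), which the real-data acceptance tier covers when
its non-redistributable inputs are supplied under `data/`. One deliberate
consequence of modelling deviation as raw coordinate noise is that torsion
validation of the noisy query reads low (≈85–90% allowed): random
displacement is precisely what bad stereochemistry looks like, whereas real
homology models are minimised; the torsion-true helix fixture (100%
favored) demonstrates the validator's calibration.

## Known limitations

- Exact reproduction of published conservation percentages depends on the
  (unpublished) similarity scheme and denominator of the original rendering
  tool; the scheme is configurable and comparisons carry ±2-point bands.
- Whether published superposition RMSDs are pruned or all-pair values is
  typically unstated; both are reported and the pruned value treated as
  primary.
- Hydrogen-bond calls at region boundaries are threshold-sensitive; the
  exact relaxations applied by interactive viewers are unpublished, so
  per-bond agreement with published figure panels may require parameter
  adjustment, which the config exposes and the reports record.
- mmCIF output, bond-order perception, symmetry-mate assembly generation,
  flexible alignment, explicit-hydrogen optimisation, π-stacking geometry
  scoring and cavity-volume computation are out of scope.
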