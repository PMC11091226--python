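# Methods

## The fragmentation scheme

A receptor–ligand complex is decomposed residue by residue. For residue
R<sup>i</sup> the package excises the capped tripeptide
C<sup>i−1</sup>R<sup>i</sup>C<sup>i+1</sup> (the caps are the covalently
adjacent residues, kept whole, no side-chain truncation) and the caps-only
system C<sup>i−1</sup>C<sup>i+1</sup>, each with and without the binder,
and combines the four energies as

IE(BID/R<sup>i</sup>) = E(BID+CRC) − E(CRC) − E(BID+CC) + E(CC).

Cuts are placed at the backbone amide C(=O)–N bond, so each residue keeps
its own amide nitrogen and carbonyl; this matches the "amine and carboxyl"
capping picture and leaves every fragment a chemically sensible peptide.
Each cut bond is saturated by one link hydrogen positioned exactly on the
original bond vector at 1.09 Å from a carbon parent and 1.01 Å from a
nitrogen parent (standard X–H bond lengths). Original atoms never move;
atoms shared between fragments are coordinate-identical bitwise, which is
what makes the cap terms cancel. Chain termini and crystallographic
sequence gaps are treated alike: the missing cap is omitted and the native
terminal group retained. Disulfide-linked cysteines are not cuttable in
this version and raise an error if excised. All fragments are closed-shell
(multiplicity 1); net charges are the sum of integer residue formal
charges (pH-7 table: Asp/Glu −1, Lys/Arg +1) plus the ligand charge.

## Pocket selection and the radius scan

Pocket membership uses the minimum heavy-atom–to–heavy-atom distance
between residue and ligand (hydrogen placement in crystal structures is
model-dependent, so heavy atoms are the robust default; the convention is
a keyword argument). Selection is monotone in r, so the half-Ångström
grid r = 0.5, 1.0, …, r_max produces nested residue sets. Every residue's
IE is computed once, at the r_max pocket, and reused at all radii — the
cumulative energy at r is simply the sum over the sphere's members.

Convergence: the smallest radius r_k with
|E(r_k) − E(r_{k−1})| / max(|E(r_k)|, 10⁻⁶) ≤ θ (default θ = 0.10) such
that the criterion also holds at every later computed radius. The
denominator floor guards all-zero series; the "holds thereafter"
requirement prevents a flat early plateau (spheres that gained no new
residues) from being read as convergence. Both choices are configurable
because the 10% rule alone does not pin them down.

## Energy backends

**Classical (verification) backend.** E = Σ over atom pairs of
332.0636·q_iq_j/(ε·r_ij) + 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶], with
Lorentz–Berthelot combining, charges in e, distances in Å, energies in
kcal/mol. The dielectric constant ε (10 and 40 by default, the values
used for continuum-solvated DFT work on receptor pockets) divides only
the Coulomb term, so Coulomb components at ε = 10 and 40 differ by exactly
×4. Because this model is strictly pairwise additive,
E(A∪B) = E(A) + E(B) + cross(A,B) holds to floating point, and with
*ghost* link atoms (q = 0, ε_LJ = 0, the default) the MFCC combination
reduces algebraically to the direct ligand↔residue cross energy — the
package's central correctness oracle, checked to 10⁻⁹ kcal/mol. With
*parameterized* link hydrogens the residual error equals exactly minus the
ligand↔inner-link-hydrogen cross term, which is asserted in closed form.
The backend caches results by fragment content hash (role, geometry to
10⁻⁶ Å, charge, multiplicity), so no fragment is evaluated twice. This
backend is a stand-in for verification and desk-scale runs, not a claim of
physical fidelity.

**External QM interface.** Production energies come from a DFT engine.
`write_qm_input` emits a Gaussian-dialect deck — route line with
method/basis and the continuum-solvent dielectric (defaults
B97D/6-311+G(d,p), CPCM), title, "charge multiplicity" line, element +
Å coordinates to 6 decimals — byte-identical for identical fragments.
`parse_qm_output` takes the last "SCF Done" (or generic "FINAL ENERGY =")
line as hartree, converts by 627.509474 kcal/mol, and flags convergence by
the normal-termination marker; unconverged or missing fragments mark their
residue failed without aborting the run, since production QM jobs fail
routinely. No BSSE/counterpoise correction is applied; the ligand is
assumed neutral unless configured otherwise.

## The synthetic generator

Toy complexes exist to make every stage testable without downloads. A
peptide (library GLY, ALA, SER, ASP(−1), LYS(+1); explicit hydrogens only
where a donor is needed) is built from internal coordinates — N–Cα
1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, extended backbone φ = −139°,
ψ = 135°, ω = 180° by default — and a probe (single LJ sphere, ±0.4 e
diatomic dipole at 1.2 Å, or an N-acetyl-amide "tripeptide mimic" with a
six-carbon ring proxy and a label/region map) is placed at a chosen offset
above an anchor residue's Cα. Charges come from an embedded table whose
per-residue sums equal the formal charges exactly, or from seeded uniform
draws shifted to the same constraint; Lennard-Jones parameters come from a
small per-element table. Any geometry with an interatomic distance below
0.8 Å is rejected as a clash. The oracle sweep uses 100 five-residue
complexes with seeded random sequences, anchors, offsets in 4–5 Å and
seeded charges — small enough that the full sweep runs in seconds on one
CPU while exercising every capping topology and both charged residues.

What the toys do *not* emulate: real ligand chemistry, receptor folds,
conformational strain, polarization or charge transfer. Passing the oracle
tests therefore certifies the *fragmentation algebra and bookkeeping*, not
the physical accuracy of any particular energy model on real complexes.

## Contact annotation

Each reported residue is annotated with its nearest ligand heavy atom
(translated through the ligand's label/region scheme when present) and a
reduced five-class geometric type: hydrogen bond (N/O donor–acceptor
≤ 3.5 Å, donor–H–acceptor ≥ 120°), non-conventional hydrogen bond (same
geometry, C–H donor), aromatic (ring-centroid distance ≤ 5.5 Å),
hydrophobic (apolar-carbon pair ≤ 4.5 Å, where "apolar" means no N/O
within covalent range), else polar contact. These are community-standard
thresholds, configurable; the richer interaction typologies of commercial
visualization software (π-alkyl, π-sulfur, dipole–dipole, …) are out of
scope and not reproduced. Annotation never alters energies.

## Numerical and design choices

* Coulomb constant 332.0636 kcal·Å/(mol·e²); hartree → kcal/mol
  627.509474.
* Altloc resolution: highest occupancy, ties to altloc 'A'; first MODEL
  only; waters and unlisted het groups dropped; author residue numbering
  preserved so residue labels match published numbering.
* Fusion-domain residues in chimeric constructs are ordinary residues; at
  10 Å they are outside the pocket and harmless.
* Classification band: |IE| < 10⁻⁶ kcal/mol is "neutral"; ranking sorts
  ascending IE with ties broken by (chain, number, icode).
* Report CSVs print 2 decimals (kcal/mol scale of interest) while all
  internal arithmetic is double precision; reruns with identical inputs
  are byte-identical.

## Known limitations

* The pocket-count comparison against deposited receptor structures is
  sensitive to the distance convention (heavy-atom minimum here) and to
  structure preparation; counts can shift by a few residues under other
  conventions. Structure preparation itself (protonation, missing side
  chains, minimization) is out of scope — inputs are assumed prepared.
* No mmCIF input; no disulfide cutting; no free-energy components
  (entropy, desolvation, strain) — the quantity is the interaction-energy
  decomposition only.
* The classical backend's absolute fragment energies are dominated by
  intra-fragment bonded-pair terms and are physically meaningless; only
  the four-term combination (where they cancel) carries meaning.
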