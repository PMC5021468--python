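# Methods

## The analysis in one paragraph

Thermophilic enzymes are frequently stabilized by surface ion pairs and
ion-pair networks, by tight intersubunit contacts, and by anchored N-
and C-terminal polypeptides.  Given crystal structures of two homologous
enzymes, the package quantifies these features and their sequence-level
correlates: it reconstructs the biological oligomer, detects
opposite-charge residue contacts under a distance criterion, classifies
them by subunit span and structural region, assembles them into
networks, measures conformational agreement by Cα RMSD at whole-chain
and domain granularity, and tabulates amino-acid composition indicators
from the deposited sequences.  The package was built around a pair of
homodimeric archaeal citrate synthases (ST1805-CS / ST0587-CS, PDB
1VGM / 1VGP) and ships their domain definitions as constants, but no
operation is specific to them.

## Ion-pair model

A residue pair (one positive, one negative) is an ion pair when the
minimum distance over their charged side-chain atoms is ≤ the cutoff.

* **Cutoff**: 4.0 Å, compared inclusively.  "Within 4 Å" conventions
  differ between studies; the inclusive reading is pinned by a test so
  the boundary behavior is an explicit contract, not an accident.
* **Charged atoms**: Arg NE/NH1/NH2, Lys NZ, Asp OD1/OD2, Glu OE1/OE2,
  His ND1/NE2.  These are the atoms that carry formal charge at neutral
  pH; no geometric hydrogen-bond test is applied.
* **Histidine** is excluded from the positive set by default: its
  protonation state at crystallization pH is ambiguous, and the named
  salt bridges in the citrate-synthase comparison all involve Arg/Lys.
  The toggle is a first-class parameter and the pipeline report always
  carries both totals (with and without His) as a sensitivity check.
* **Counting unit** is the residue pair: a bidentate Arg–Glu contact
  with four sub-cutoff atom distances is one ion pair.  This matches
  how such counts are reported in the comparative-structure literature.
* **No sequence-separation filter**: adjacent residues that satisfy the
  criterion are counted.  Intra-residue and like-charge contacts are
  excluded by construction.
* Residues whose charged side-chain atoms are all unmodeled (disorder)
  are skipped with a warning rather than treated as absent silently —
  the warning stream is the audit trail for inclusion decisions.
* Detection uses a k-d tree over charged-atom coordinates with a
  relative slack of 1e-9 on the query radius, then exact distance
  filtering, so tree pruning can never drop an exact-boundary contact.

Dimer-level totals are computed on the biological assembly, never on
crystal neighbors: contacts to symmetry mates outside the deposited
assembly are crystal packing, not oligomer chemistry.

## Region classification and the interterminal label

Each chain carries interval sets for the large domain, small domain,
N-terminal and C-terminal regions; terminal labels take precedence over
domain labels when they overlap, because for ion-pair bookkeeping the
terminal identity is the informative one.  A pair is **interterminal**
when it spans two subunits and both partners carry terminal labels.

When no domain definitions are supplied, a heuristic default labels the
first 60 residue numbers of a chain as N-terminal and the last 25 as
C-terminal.  The C-terminal width covers the extended C-terminal arm of
the citrate-synthase fold; the N-terminal width extends through the D
and E helices (to about residue 60) because the documented interterminal
partners of the C-terminal arm sit there (e.g. glutamates at positions
45–56 and arginines at 58–60 on the partner subunit).  A narrower
N-terminal window (e.g. the first 35 residues) would exclude several of
those partners and silently shrink the interterminal count.  Both widths
are ordinary parameters, overridable per chain; for serious use supply
real domain intervals (the two isozymes' intervals ship as
`ST1805_DOMAINS` / `ST0587_DOMAINS`).

Networks are connected components of the graph whose vertices are
charged residues and edges are detected pairs, reported largest-first.
Components of size 2 are retained (they are the simple pairs); the
conventional "network" reading is size ≥ 3 and callers filter on size.

## Structure handling

* **Parsing** is delegated to gemmi; the package model keeps author
  residue numbering everywhere (published residue labels are author
  numbers), SEQRES as one-letter sequences, the unit cell, and the
  biological-assembly operators.  A fixed-column validator rejects
  malformed ATOM/HETATM numeric fields with the offending line number,
  which the underlying parser would otherwise tolerate.
* **Altlocs**: downstream geometry sees one conformer per atom name —
  highest occupancy wins, ties go to file order.  Published atom counts
  for such models assume single positions, so the audit counts use the
  same rule.
* **Hydrogens** are dropped at read time; all criteria use heavy atoms.
* **Assemblies** come from the deposited BIOMT operators only; deriving
  mates from space-group symmetry is out of scope.  Requesting an
  assembly from a file without operators is an error, never a silent
  monomer.  Generated chains get `-2`, `-3`… suffixes so every copy
  traces to its source chain (the PDB writer remaps such ids onto free
  single letters, since the format has a one-character chain field).
* **Model audit** (`model_stats`) reports what was parsed —
  altloc-deduplicated heavy-atom counts for polymer residues, water and
  hetero-group counts, modeled residues per chain.  Where a
  publication's prose and its tables disagree about such counts, the
  parsed file is the authority and the audit simply reports it.

## Superposition

Closed-form Kabsch via SVD with reflection correction (the smallest
singular axis is negated when det < 0), so the result is always a
proper rotation.  All reported figures are Cα-only RMSDs.

Correspondence is the substantive choice:

* within a homodimer, chains share author numbering, so residues are
  paired by number (residues missing a Cα drop from both sides);
* across homologs there is no shared numbering; the only reproducible
  pairing at ~45 % identity is alignment-derived.  The package aligns
  the ATOM-derived sequences with the default alignment parameters and
  pairs the non-gap columns that have Cα on both sides.  The
  correspondence used is attached to every result.

Because published RMSD figures rarely state their pairing and inclusion
rules, regression tests against published values use ±0.05 Å
(same-protein) and ±0.1 Å (cross-protein) tolerances rather than exact
agreement.  The pipeline reports all chain-pair combinations across two
structures rather than guessing which one a publication used.

## Alignment and composition

The Gotoh three-state dynamic program implements global
Needleman–Wunsch with affine gaps.  Conventions, all pinned by tests:

* gap of length L costs `open + (L−1)·extend` (EMBOSS/Biopython
  convention); end gaps are penalized (true global alignment);
* traceback ties break deterministically diagonal → up → left, so the
  emitted alignment string is reproducible across platforms;
* defaults BLOSUM62, open 10, extend 0.5;
* percent identity defaults to the shorter-sequence denominator, with
  the aligned-columns value reported alongside as sensitivity output.
  The denominator rule is carried in the result object because
  "percent identity" without its denominator is ambiguous.

Scores agree exactly with Biopython's `PairwiseAligner` on random
sequences and with an exhaustive alignment enumerator on short strings;
the in-package implementation exists because the deterministic
traceback and the audit-ready correspondence are contracts here, not
incidentals.

Composition tables count the 20 standard residues; unknown (`X`)
residues enter the total but no bin, with a warning.  Percentages are
rounded to one decimal (the convention of published composition
tables), and indicators are sums of rounded percents: Glu+Lys,
Asn+Gln, Cys+Met, and all-charged D+E+K+R+H.  Composition uses the full
deposited (SEQRES) sequence, not just modeled residues — published
totals refer to the full chains, and disordered termini would otherwise
bias the counts.  The comparison report flags indicator orderings only;
with a handful of sequences there is nothing to test statistically.

## Synthetic fixtures: what they do and do not show

The generator emulates the *bookkeeping and geometric* features of real
deposited structures: multi-chain files, charged residues at controlled
side-chain distances straddling the cutoff, a second subunit by a known
rigid transform (explicit chain or BIOMT operators on a monomer),
SEQRES supersets of modeled residues (disordered N-termini), waters and
glycerol/sulfate hetero groups, and real PDB residue/atom naming so the
production code path runs unmodified.

Construction guarantees: the planted minimum charged-atom distance is
exact in memory (file round-trip adds ≤ ~3 × 10⁻³ Å from the format's
3-decimal coordinates); the emitted truth manifest is re-derived from
final coordinates by an exhaustive double-loop scan, so incidental
contacts are part of the truth rather than violations of it; infeasible
specifications (a residue in two planted pairs, indices closer than 5
positions) are rejected before emission; identical spec + seed gives
byte-identical files.

Deliberate non-goals: backbones are idealized helices without real
stereochemistry, side-chain atoms are placed for distance control
rather than rotamer realism, and there is no crystal packing, solvent
shell structure or B-factor/occupancy realism.  Green tests on these
fixtures therefore demonstrate algorithmic correctness — detection,
classification, networking, superposition and parsing behave exactly as
specified on structures with known truth — not that any particular
biological conclusion holds; conclusions about real proteins require
the real coordinate files, which the structure-dependent regression
checks consume when placed under `data/`.

`perturb_structure` drives the hinge tests: it rotates a residue
interval rigidly about the z-axis through the interval's first Cα and
jitters everything else with Gaussian noise, so domain-wise
superposition must return to numerical zero while whole-chain RMSD
grows — the signature of rigid-body domain motion.

## Problem sizes and runtime

The test and acceptance workloads use 20 seeded fixture dimers of
60–100 residues per chain for the detection oracle, 15-point sets over
20 seeds for rigid-transform recovery, a 20°-grid + simplex-refined
rotation search on 10-point sets as the superposition oracle, and
exhaustive alignment enumeration for strings up to length 8 over a
4-letter alphabet (complete enumeration of all pairs is restricted to
lengths ≤ 3; longer pairs are a seeded random sample, since the full
pair space grows combinatorially).  These sizes give full coverage of
the contracts at interactive runtimes; all quantities scale to real
protein sizes through the same code paths.

## Known limitations

* No electrostatic energies, pKa shifts or low-pH corrections: the
  distance criterion is geometric, and at strongly acidic physiological
  pH surface carboxylates may be protonated — surface-network counts
  should be interpreted accordingly.
* No solvent-accessibility calculation; "surface" versus "buried" is
  not computed, only region labels.
* Residue correspondence across homologs inherits any alignment error;
  alternative gap parameters can shift cross-protein RMSD within the
  stated tolerance.
* Author numbering is trusted; insertion codes are carried but the
  shipped domain constants assume none.
* The default terminal windows are heuristics for this enzyme family;
  other folds need their own intervals.
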