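# Methods

## The modelling procedure

`pmhcdock` models a peptide:MHC-I complex from the epitope's linear
sequence under one central assumption: within an MHC-I allotype, bound
epitopes of a given length share a characteristic backbone conformation, so
a crystallographic *epitope pattern* can supply the backbone and the
modelling problem reduces to placing side chains and refining the pose in
the cleft. The workflow is dock → minimize → re-dock:

1. **Threading.** Backbone atoms (N, Cα, C, O; terminal OXT when the
   pattern has one) are copied verbatim from the pattern — the threaded
   backbone RMSD to the pattern is exactly 0 by construction, no fitting.
   Cβ is copied from the pattern when present (never for Gly), otherwise
   constructed at tetrahedral geometry (C–N–Cα–Cβ torsion −122.6°, 1.53 Å).
   Remaining side-chain heavy atoms are built by NeRF placement from a
   per-residue internal-coordinate table (`pmhcdock.topology`) in a single
   common rotamer: χ1 = −60° (gauche−), aliphatic χ2+ trans, planar ring
   torsions, Thr χ1 = +60°. No combinatorial packing is attempted — side
   chains are the only degrees of freedom the docking stages refine, so the
   initial placement only needs to be chemically sane; the topology audit
   (`audit_topology`) verifies heavy-atom completeness for all 20 residues.
2. **Epitope relaxation.** A brief minimization of the lone peptide with
   the backbone frozen. The mock backend implements this as deterministic
   soft-sphere clash relief: non-bonded heavy-atom pairs (excluding
   same-residue and adjacent-residue pairs) closer than 2.0 Å are pushed
   apart along their separation vector (margin 0.05 Å, ≤100 sweeps), moving
   side-chain atoms only. Clash-free input is returned bit-identical.
3. **Docking (D1).** The search box is anchored on the epitope pattern:
   bounding-box midpoint of its heavy atoms, dimensions equal to the
   extent plus 2 × 8 Å padding per axis (the midpoint, not the centroid,
   guarantees the pattern is contained for every padding, including the
   tight padding-0 box). The backend contract is: receptor rigid, peptide
   backbone rigid, side chains flexible, `n_runs` independent runs
   (default 20), one best pose per run with a binding energy in kcal/mol
   (lower = better).
4. **Cleft screening.** Each pose must keep ≥90 % of its heavy atoms inside
   the box, both terminal Cα atoms within 6 Å of the pattern's termini, and
   a positive normalized projection of its N→C axis on the pattern's. The
   three thresholds are explicit `CleftCheckParams` knobs; they quantify an
   otherwise qualitative position/orientation check and are chosen to
   reject the two canonical failure modes (pose outside the cleft, pose
   inverted or with a protruding terminus) while accepting every pose that
   differs from the pattern by side-chain movement plus the mock docker's
   small rigid jitter. Screening is applied per pose before consensus —
   stricter than screening only the selected pose — and a stage with zero
   surviving poses aborts the run with a report.
5. **Consensus selection.** Cut-off *Co* = arithmetic mean of the
   ensemble's binding energies; poses with BE ≤ *Co* are retained (non-
   strict, so the all-equal ensemble keeps everything, and the minimum-BE
   pose always survives since min ≤ mean). Retained poses are compared
   all-vs-all by Kabsch-superposed heavy-atom RMSD; the pose with the
   lowest mean RMSD to the other retained poses (mean excludes self and
   excludes filtered-out poses) is selected, with exact ties broken by
   lower BE, then lower run index. The selection is verified against
   exhaustive row-mean enumeration in the acceptance suite.
6. **Complex minimization (EM).** The selected pose is merged with the
   receptor and minimized with all residues mobile. `EMConfig` carries the
   external-engine protocol (cubic solvated box, SPC water, 0.15 mol/L
   NaCl, GROMOS53a5, 1.0 nm non-bonded cut-offs, steepest descent, ≤10 000
   steps, 0.001 nm initial step, 2 000 kJ mol⁻¹ nm⁻¹ force tolerance); the
   mock backend applies the same soft-sphere relief as step 2 with all
   atoms mobile.
7. **Docking (D2).** Re-run of steps 3–5 against the minimized receptor and
   peptide, through the identical code path with an independent seed
   stream. The final complex is written in PDB format with the peptide as
   chain `P`.

Randomness: one master seed; per-stage seeds derive from
`SeedSequence([master, stage_index])` and per-run streams from
`default_rng([stage_seed, run_index])`, so D1 and D2 are independent and
the whole pipeline is bit-reproducible with the mock backends.

## Evaluation

A model is compared to a reference crystal by superposing the MHC chains —
Cα atoms of heavy-chain residues shared by residue number, plus
β2-microglobulin when both structures carry one (it is absent from some
entries) — then measuring the epitope RMSD without further fitting, over
Cα and over all heavy atoms. "All atoms" means heavy atoms: crystal
references lack hydrogens and hydrogen bookkeeping is engine-specific.
Target atoms missing to disorder are dropped pairwise from the all-atom set
with the compared count recorded. A model passes at Cα RMSD ≤ 2.0 Å
(non-strict: 2.000 passes, 2.061 does not).

Benchmark aggregation groups records by (allotype, epitope length):
n, mean, sample s.d. (n−1), s.e.m. = sd/√n, median and 25–75 % IQR by
linear interpolation, plus a pooled TOTAL row. Because the TOTAL is
computed from the same records, its mean equals the count-weighted mean of
the group means to full precision; the published validation summary rows in
`pmhcdock.refdata` reproduce their printed overall means through exactly
this identity (to within one ulp of the 3-decimal printed table, since the
printed group means are themselves rounded: the pooled all-atom mean is
1.9647 against a printed 1.964).

## Synthetic fixtures and what they do (not) show

The toy complex is geometry, not chemistry: an ideal-geometry extended
poly-alanine peptide (φ/ψ = −139°/135°) lying along the groove axis,
flanked by two straight chain segments at y = ±7 Å with floor segments at
z = −6 Å standing in for the α1/α2 walls (180 residues, chain A), plus an
optional 99-residue β2m-sized chain. It satisfies every structural
precondition downstream modules state (roles assignable, peptide inside the
default box, clash-free) and every generator is a pure function of its
spec. Benchmark fixtures translate the peptide rigidly by a known amount
after snapping coordinates to the PDB's 3-decimal grid, so the evaluated
RMSD equals the injected displacement to ~1e-14 even through a file
round-trip (displacements should be multiples of 0.001 Å).

Passing on these fixtures demonstrates that the geometry, selection logic,
bookkeeping and error handling are exact; it does not validate docking
energetics, real MHC groove chemistry, or the behaviour of external
engines — those enter only through the backend adapters and real template
structures, and reproducing the crystal-benchmark statistics requires both.

## Numerical choices

- Kabsch superposition via `scipy.spatial.transform.Rotation.align_vectors`
  (proper rotation enforced; mirror solutions excluded); degenerate inputs
  (<3 atoms, collinear sets) raise. Orthonormality asserted at 1e-6–1e-8.
- RMSD is plain unweighted atomic RMSD; values are kept at full precision
  internally and rounded to 3 decimals only at presentation.
- Consensus tie detection uses a 1e-9 window on row means before the
  BE/run-index tie-break.
- Alternate locations: blank > 'A' > highest occupancy. Hydrogens are
  dropped at sanitization. Non-standard residues map to standard parents
  via a small table (MSE→MET, HYP→PRO, …); unknown polymer residues raise.
- The peptide chain is identified by the 8–12-residue length window
  (shortest candidate; equal-length candidates are an error), the heavy
  chain as the longest protein chain, β2m as a remaining 90–110-residue
  chain — chain ids are too inconsistent across entries to rely on.
- Mock docking binding energy: −0.05 × (receptor heavy-atom contacts
  within 4 Å) + Gaussian noise — enough structure to make the cut-off
  filter meaningful, with no physical claim.

## Problem sizes

The test suite and acceptance script run entirely on synthetic inputs:
toy complexes of ~290 residues, ensembles of up to 20 poses, 1000
random consensus matrices, 200 random Kabsch trials, and mock pipeline
runs with 3–20 docking rounds. The full suite completes in a few seconds
on one CPU.

## Known limitations

- Length-matched threading only: no insertions/deletions relative to the
  pattern, no loop modelling, and epitopes with genuinely unusual (e.g.
  bulged) backbones inherit the pattern's conformation regardless.
- Single-rotamer side-chain construction can start sterically strained for
  bulky residues; the pipeline relies on relaxation and docking to fix it.
- First model only of multi-model files; no mmCIF; no nucleic acids.
- External adapters prepare engine inputs and drive execution but do not
  parse every engine's output dialect; real-engine runs feed poses back
  through `load_ensemble` (directory of pose PDBs + BE table).
- The cleft check judges position and orientation only, never binding
  affinity or pocket-level physicochemical compatibility.
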