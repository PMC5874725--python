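# Methods

## Model and assumptions

The Gaussian Network Model treats a folded chain as a network of isotropic
Gaussian springs between Cα atoms closer than a cutoff distance. All
dynamics derive from the Kirchhoff (graph Laplacian) contact matrix Γ; mode
*k* has eigenvalue λ_k and shape u_k. Because Γ is a Laplacian, λ ≥ 0 and
the number of (numerically) zero eigenvalues equals the number of connected
components of the contact graph; for a well-formed chain there is exactly
one. The per-residue weighted fluctuation sum over a mode set is normalized
to unit total, which cancels the physical prefactor k_B·T/γ — the package
therefore sets it to 1 and all amplitude thresholds are fractions of the
total, not absolute displacements.

The biological premise: the fastest modes concentrate on densely packed,
kinetically hot residues; in heterodimers (especially with very different
chain lengths) at least one partner's binding patch and its supporting
scaffold sit at or around such residues, so spreading hot-residue influence
to sequence and space neighbours recovers contact plus first-layer residues.

## Parameters

| parameter | default | meaning |
|---|---|---|
| Kirchhoff cutoff | 7 Å | Cα–Cα contact distance of the elastic network (inclusive) |
| contact cutoff | 4.5 Å | atom–atom distance defining interchain contacts and first-layer membership (inclusive; ≈ one water diameter) |
| hot threshold | 0.05 | normalized amplitude above which a residue is hot (strict >) |
| 1D half-width | 4 / 3 | sequence spread; 4 for chains > 100 residues, else 3 |
| 3D cutoff | 6 / 8 Å | spatial spread; 6 Å for chains < 250 residues, else 8 Å |
| too-many bound | 0.60 / 0.50 | upper prediction-fraction band edge; 0.60 for length ≤ 300 |
| too-few bound | 0.40 / 0.20 | lower band edge; 0.40 for length ≤ 500 |
| reversal limit | 1 | direction reversals allowed in the adjustable loop |

"Length" is always the number of residues with a resolved Cα — the elastic
network sees nothing else. All defaults are overridable per run
(`--config`, or the keyword arguments of `SpreadPolicy.for_length` /
`AdjustableConfig.for_length`).

## Numerical and procedural choices

* **Eigensystem.** Dense symmetric eigendecomposition (LAPACK via
  `scipy.linalg.eigh`); eigenvalues clipped at 0 to remove round-off;
  eigenvector signs fixed by making each vector's largest-magnitude
  component positive, so results are bit-reproducible. Zero modes are
  detected at 1e-8 relative to the largest eigenvalue.
* **Top-decile mode count.** m = |{k : λ_k ≥ λ_max − 0.1·(λ_max − λ_min)}|
  with λ_min the smallest eigenvalue including the trivial zero mode. For
  folded chains λ_max ≫ λ_min so the alternative convention (smallest
  non-zero λ) almost never changes m; the choice is exposed through the
  spectrum object should anyone care to compare.
* **Fast-mode selection ties** break by descending eigenvalue, then
  ascending mode index (the natural order of the sorted spectrum read from
  the top).
* **Adjustable loop.** The profile, hot set and spread are recomputed in
  full at every mode count; the band test is inclusive (a fraction exactly
  at a bound is in band). A *reversal* is a change of step direction; when
  a second reversal would occur the loop returns the last computed
  prediction flagged `reversal_limit`, and `mode_bounds` flags walking out
  of the valid mode range [1, n − #zero-modes]. The trace of (m, fraction)
  pairs is part of the result and replays exactly through
  `fixed_mode_predict`.
* **Residues without coordinates.** Residues present in sequence but
  missing from the model keep their slot in the residue list: they absorb
  1D window positions (a gap really does separate its sequence neighbours)
  but are never predictions, targets, or network nodes.
* **Altlocs / models / modified residues.** Model 1 only; highest-occupancy
  altloc (ties: first in file); MSE and other common modified residues map
  to their parent type, unknown types become UNK — kept for geometry,
  rejected by statistical-potential lookups. Hydrogens are excluded from
  all contact tests (the structures this protocol targets rarely resolve
  them, and mixed protonation would shift boundaries inconsistently).
* **Degenerate evaluations.** `evaluate_chain` requires
  0 < targets < chain length, since both ratios are otherwise undefined.
  The decoy pipeline instead uses a lenient variant — zero targets give
  TP = 0, an all-target chain gives FP = 0 — because fully separated decoys
  have empty interfaces by construction; the standing formula is unchanged.
* **Decoy ranking.** Ascending standing, ties broken by decoy id; the
  per-decoy chain selection is 'a', 'b' or 'min' (both-chain reporting is
  the default in the evaluate command, 'min' gives a single number per
  decoy). Near-native counts include the native structure itself.
* **Statistical potential.** The energy table is user input; the default
  contact rule is any-atom at 4.5 Å, matching the target definition, with
  Cα-only and Cβ (Cα fallback for glycine) rules available since published
  residue-level potentials differ in their contact conventions. Only the
  ordering of decoy energies matters downstream; units are whatever the
  matrix supplies.

## The synthetic-fixture generator

`synthetic_fixtures` builds three deterministic toy geometries from Cα
traces with one pseudo side-chain atom per residue (1.5 Å, alternating
orientation): facing extended strands (closed-form contact sets, used as
exact oracles), parallel ideal α-helices, and the default `grid_patch` — a
snake-packed 3D block of 60 residues with a flat 12-residue patch docked
5.2 Å above its top face. The block's packed core gives the degree contrast
that localizes fast modes in real folds; a small seeded in-plane jitter
(±0.15 Å) breaks the lattice's translational degeneracy, while the
interface normal stays exact so that the native pose keeps the maximal
contact set under any near-native move (there is no steric repulsion term
that would otherwise forbid interpenetrating poses).

Decoy sets mirror published rigid-body sets: 110 decoys, the native pose
first, nine further near-native poses (in-plane slides ≤ 0.5 Å and twists
≤ 0.5° of the docked patch), and far poses placed well outside contact
range with arbitrary orientation. By construction near-native decoys retain
interchain contacts, far decoys have none, and the native complex has the
lowest interface energy under any attractive pair potential.

What the toys do **not** emulate: real side-chain packing, irregular
secondary structure, surface solvation, or the empirical decrease of target
fraction with chain length. In particular the prediction band
(0.40–0.60 of the chain) was calibrated against real-protein target
fractions; toy hosts larger than ~60 residues have proportionally smaller
interfaces, so the adjustable loop saturates at `mode_bounds` with a high
false-positive ratio there. Passing tests therefore demonstrate the
machinery — extraction, spectra, spreading, loop control, ranking — not
prediction accuracy on real dimers, which requires curated PDB sets outside
the scope of the test suite.

## Problem sizes

The test suite and the acceptance script run on 8–120-residue chains,
200-fixture property sweeps, and one full 110-decoy set; everything
completes in seconds on one CPU. Larger structures only grow the dense
eigendecomposition (O(n³); a 1000-residue chain takes well under a minute).

## Known limitations

* Isotropic GNM only — no anisotropic network, no slow-mode/global-motion
  analysis, no homodimer-specific treatment.
* The expected-target band is a step function of length with fixed edges,
  not a fitted curve.
* Near-nativeness of decoys is label input; no RMSD computation.
* mmCIF input is not implemented; the PDB dialect is the contract.
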