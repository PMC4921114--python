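# Methods

`noefold` determines small-protein structures from NOESY cross peaks by
iterating between automated (ambiguous) NOE assignment and restrained
simulated annealing, with optional assistance from homologous template
structures. This note records the model, its parameters, and the design
choices made where the procedure was genuinely open.

## Ambiguous assignment and the r⁻⁶-summed distance

Every 3D NOESY cross peak (two ¹H shifts plus one ¹³C/¹⁵N shift) is
explained by all atom triples whose assigned shifts fall within matching
tolerances (defaults 0.03 ppm for ¹H, 0.4 ppm for the heavy dimension,
community practice) with the heavy atom covalently bonded to the first
proton. A peak with several explanations becomes one ambiguous restraint
whose effective distance is

    d_eff = ( Σᵢ dᵢ⁻⁶ )^(−1/6)  ≤  min(dᵢ),

so the closest candidate pair dominates and a restraint is satisfied
whenever any of its explanations is.

Upper limits come from the usual NOE intensity law, anchored at the
median intensity of each peak list:

    u = 3.6 Å × (I / I_med)^(−1/6),  clipped to [2.4, 5.5] Å,

plus CYANA-style pseudoatom corrections (+1.0 Å per methyl, +0.7 Å per
methylene pseudoatom member) and hard bounds [1.8, 7.0] Å. The 3.6 Å
anchor is the package's calibration choice; it is deliberately simple and
means limits are only as tight as the peak-intensity statistics allow.

## Endurance scoring

Each restraint carries an endurance score (assignment confidence), a
supportive score (template evidence) and a recycle-bin flag.

* Initial endurance: `E₀ = 10 / n_candidates × q`, with `q` the mean over
  the three dimensions of `1 − |shift error|/tolerance`. Unambiguous,
  exactly-matching peaks start at 10; heavily ambiguous ones near 0.
* Supportive score: `S = 3 × Σ_templates f_tri`, capped at 9 (capped at 3
  when a single >80 %-identity template is in use, so one close homolog
  cannot lock a constraint in). `f_tri` is the local-match weight of the
  supporting template: 1.0 when the aligned tripeptide around the contact
  is identical, 0.5 when only the central residue matches, 0 otherwise; a
  two-residue contact uses the weaker of its two ends.
* Category: combined score ≥ 8 → robust, ≥ 4 → intermediate, else
  uncertain.
* Update: after each cycle of 20 models,
  `E ← E − 2 × f_viol × clamp(mean_violation / 1 Å, 0, 2)`, where
  `f_viol` is the fraction of models violating the limit by > 0.2 Å and
  the mean is taken over violating models. Scores never increase. A
  constraint whose combined score drops below 0 moves to the recycle bin;
  bin members that a *later* model (computed without them) satisfies
  within 0.2 Å re-enter with the endurance score reset to exactly 0, so a
  repeat offender is removed again immediately.

The score magnitudes (10, 3, thresholds 8/4, penalty 2, 0.2 Å) are this
package's concrete instantiation of the published qualitative behaviour;
they live in one config block (`ScoringParams`) and are exercised directly
by the tests.

## Template assistance

Templates are aligned globally (Needleman–Wunsch, BLOSUM62, gap open 10 /
extend 0.5) and ranked by identity over aligned non-gap columns. Selection
follows the published rules exactly: best identity < 20 % → no prediction;
> 80 % → that single template only; otherwise the top three. Hydrogens are
added to template coordinates with ideal geometry (amide H at 1.01 Å in
the peptide plane, Hα tetrahedral at 1.09 Å, side-chain protons beyond Hα
as pseudoatoms at their carbon positions). All interproton pairs below
5.5 Å whose residues both align, with ≥ 1 residue separation in target
numbering, are tabulated and then filtered against the experimental peak
lists; only contacts matched by at least one peak contribute supportive
score. Intra-residue template contacts are dropped — they carry no
structural information.

## Torsion constraints

Only strong and generous TALOS-style predictions are used. Predicted
deviations are clamped into [10°, 35°] (≤ 10 → 10, > 35 → 35); initial
half-widths are ±2× the clamped deviation for strong and ±3× for generous
predictions. When a constraint is violated (wrap-aware, shortest arc) in
≥ 30 % of the ensemble (6 of 20 at the default ensemble size), both limits
move outward by `1.2 × V_diff × N_viol / ensemble_size` degrees, where
`V_diff` is the average violation over violating models. Expansion
compounds across cycles but the half-width is capped at 180°.

## Dynamic hydrogen bonds

Helix rule: residues `i..i+4` with all sequential HN–HN peaks and an
Hα(i)–HN(i+3) peak propose N–H(i+4)→O(i). Sheet rule: cross-strand
HN(i)–HN(j) (|i−j| ≥ 3) plus Hα(i)–HN(j) proposes N–H(j)→O(i). Only
unambiguously assigned peaks count, and duplicates merge. Proposed bonds
are idealized as H···O ≤ 2.3 Å and N···O ≤ 3.3 Å; after each cycle they
are re-measured on the best model and kept only within +0.4 Å slack
(2.7 / 3.7 Å). Eliminated bonds stay eliminated for the rest of the run.
Emitted H-bond restraints carry a static NOE potential weight of 30. The
peak patterns and the distance values are this package's instantiation of
"idealized" — the published description names no cutoffs.

## Annealing engine

The engine is a deliberately lightweight Cartesian annealer — it replaces
a full molecular-dynamics refinement package and claims no force-field
fidelity. Each residue contributes N, H (except proline), CA, HA, C, O
and one side-chain pseudoatom QB (except glycine). The energy is a sum of
non-negative penalties:

* bonds, angles and improper/peptide torsions, harmonic about ideal
  values measured from the package's own internal-coordinate builder (so
  generator and engine agree by construction);
* flat-bottom quadratic distance restraints on `d_eff` (upper and 1.8 Å
  lower bounds);
* wrap-aware flat-bottom dihedral restraints;
* H-bond distance terms at weight 30;
* soft-sphere repulsion between atoms more than three bonds apart
  (1.7 / 2.0 / 2.7 Å cores for H–H / H–heavy / heavy–heavy).

Force constants: `k_bond 100, k_angle 60, k_improper 30, k_dihedral 80`
versus `k_distance 1` and `k_repulsion 10` (energy per Å² or rad²,
arbitrary units). The deliberate stiffness hierarchy — covalent geometry
and torsions ≫ NOE terms — is what makes the scoring system work: a
restraint inconsistent with the remaining data cannot bend the model into
compliance and therefore stays measurably violated, which is the signal
the endurance update consumes. With a flat hierarchy the annealer
accommodates wrong restraints silently and error rejection degrades.

Each model starts from a random-coil build (ideal local geometry, uniform
random φ ∈ [−180°, 0°], ψ ∈ [−180°, 180°]) and runs 2000 overdamped
Langevin steps, `x ← x − η∇E + √(2ηT) ξ`, with step size η = 5·10⁻⁴ and a
geometric temperature decay from 50 to 0.01 (reduced units), followed by
an L-BFGS polish. Model k of a run uses seed + k; all randomness flows
through `numpy.random.default_rng`, and the inner loop is JIT-compiled
(numba, `fastmath` off) so results are bitwise reproducible.

## Four-phase orchestration

Phase I anneals with robust constraints only (plus torsion and H-bond
terms); an empty robust set is an error pointing at the matching
tolerances. Phase II admits intermediate constraints, phase III the
uncertain ones; newly recruited constraints violating the previous
phase's lowest-energy model by > 2.0 Å (phase II) or > 1.0 Å (phase III)
are discarded before annealing. Each phase runs 3 cycles of 20 models by
default; every cycle updates scores, processes the recycle bin, expands
violated torsion limits and re-evaluates H-bonds. Phase IV freezes the
final constraint set and refines the transferred ensemble by
minimization (the first copies unperturbed — refinement never increases
restraint energy — the rest jittered by 0.3 Å), keeping the best 20 of 40
(or 20 of 100 in final-step mode). Active set, recycle bin and discarded
set partition all constraints ever created; the per-cycle log and the
score ledger make every transition auditable.

## Synthetic data

The fixture generator emulates the complete input bundle at desk scale:
ideal-geometry toy folds (α-helix −57°/−47°, hairpin with a type-I′ turn,
helix-loop-helix), per-atom-type canonical chemical shifts with
deterministic per-residue jitter (±0.3 ppm for ¹H; ±3 ppm for ¹³C/¹⁵N,
scaled so the heavy dimension stays informative relative to its 0.4 ppm
tolerance), NOESY peaks for every proton pair under 5.0 Å with d⁻⁶
intensities (lognormal noise σ 0.2, Gaussian shift noise 0.003 /
0.05 ppm), TALOS-style predictions matching the generating topology
(deviation 12°, class strong), and homolog templates mutated to a
requested alignment identity (±2 %) with 0.3 Å coordinate noise.

Planted wrong peaks pair real atoms more than 6.5 Å apart and are
additionally required to be wrong *as constraints*: the r⁻⁶-pooled truth
distance over every credible assignment of the planted triple must
exceed 5.5 Å. Otherwise a "planted" peak can coincide with a genuine
close pair and is, by construction, a correct NOE.

What the generator does not emulate — spin diffusion, realistic
lineshapes and overlap, solvent artifacts, aromatic side chains, full
side-chain proton chemistry, residue-specific shift distributions —
bounds what passing tests show: the pipeline's bookkeeping, scoring
dynamics and geometric reconstruction are validated; performance on real
spectra is not claimed.

## Problem sizes and numerical choices

The test and acceptance studies use a 12-residue helix (two peak lists,
≈ 290 peaks, ≈ 330 constraints) and, for template thresholds, a
30-residue target where 20 % identity is exactly representable (6 of 30
matched columns). Planted-error studies run five fixture seeds at 5 %
planted peaks with database assistance on (templates at 65/50/40 %
identity). Ties in model selection are broken by stable sort on energy;
degenerate geometry in dihedral/angle gradients is guarded at 10⁻⁶–10⁻¹²;
dihedral arithmetic is wrap-aware everywhere (shortest arc).

## Known limitations

* The reduced atom representation cannot express side-chain–specific
  NOEs beyond one pseudoatom per residue.
* The annealer's schedule and force constants are tuned for desk-scale
  polypeptides (≲ 30 residues); larger systems would need longer
  schedules and neighbor lists.
* Upper-limit calibration against the median intensity compresses models
  slightly when the median pair distance differs from the 3.6 Å anchor;
  accuracy below ≈ 1 Å backbone r.m.s.d. should not be expected from it.
* Symmetric homodimers and intermolecular NOEs are out of scope.
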