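# Methods

## Scope and model

`barrelgate` analyzes trajectories of a membrane-embedded β-barrel carrying
a lateral opening in its wall, together with an optional lipid passenger
anchored inside the barrel channel. The analyses make no assumptions about
how the trajectory was produced; they require only an ordered set of frames
over one fixed atom set, in Å, with optional frame times in ns. Residue
numbers are taken verbatim from the input file (author numbering, 1-based,
inclusive ranges) and are never renumbered — removing a signal peptide does
not shift the mature chain's numbering, so published residue pairs remain
addressable.

The default domain map follows the GfcD architecture: signal peptide 1–18,
N-terminal 12-stranded barrel 19–278, periplasmic middle domain 279–423,
C-terminal 13-stranded barrel 424–698, with the C-terminal plug 674–698
folded back into that barrel (an intentional overlap).

## Superposition, RMSD, RMSF

Rigid fits solve the orthogonal Procrustes problem restricted to proper
rotations via SVD of the covariance of the centered point sets; a
reflection-optimal case is resolved by flipping the smallest singular
direction, so the rotation determinant is always +1. Degenerate inputs
(< 3 points, collinear sets) are rejected rather than silently fit.

"Backbone" defaults to N, CA, C — the convention under which most published
membrane-barrel RMSD values are computed — and is configurable; carbonyl O
can be added by passing a wider atom-name set. Mass weighting is off by
default: on backbone-only selections the masses are nearly uniform, and the
flag exists for users who want it.

RMSF uses the standard mean-structure reference with one alignment
iteration: frames are aligned to frame 0 on the alignment selection, a mean
structure is formed, and the original frames are re-aligned to that mean.
The per-atom value is the root-mean-square displacement from the mean
position; per-residue values (the default) average over each residue's
selected atoms, with a per-atom mode available. For isotropic per-coordinate
noise of width σ the expectation is E‖Δr‖² = 3σ², i.e. RMSF → σ√3, which is
the closed form the recovery tests check against.

## Gate aperture and closure

The aperture is tracked as Euclidean Cα–Cα distances for user-declared
residue pairs spanning the opening. Pairs are keyed by residue *number*
only; the residue name found is logged but not checked, because predicted
models and published figure labels occasionally disagree on identity while
agreeing on numbering. "Closed" is operationalized as a pair distance below
a configurable `closure_threshold`, default 6 Å (approximately two Cα van
der Waals radii plus a strand-pairing distance). Because any single
threshold is a convention, reports always include the per-pair
below-threshold frame fractions, so the verdict can be re-derived under any
other threshold from the same table.

## Gate plane, flicker, insertion, egress

A single oriented plane stands in for the gate mouth: the least-squares
plane through the gate-flanking Cα atoms (smallest-variance direction of
the point cloud), with its normal flipped to point away from a declared
barrel-axis point — outward, into the membrane. All side-of-membrane
decisions are signed distances to this plane.

- **Flicker depth** is, per frame, the maximum distance by which a
  membrane-lipid atom reaches past the plane on the inward (channel) side,
  clamped at zero, counting only atoms within `gate_region_radius`
  (default 8 Å) of the nearest flank Cα so that bulk bilayer lipids cannot
  register. The plane-based depth is a declared convention of this package;
  other depth definitions (from the gate residues, from the channel axis)
  would differ by geometry-dependent offsets.
- **Membrane insertion** is an *atom-count* fraction: a tail atom is
  inserted iff its signed distance is positive. Area-based estimates used
  elsewhere depend on probe radii and surface algorithms; the atom-count
  proxy is deterministic, testable, and monotone under outward motion of
  any atom, and all outputs label it as an atom fraction. Only
  aliphatic-tail atoms are counted by default (the head group is the part
  that should *not* insert). The overall fraction pools all tail atoms and
  therefore equals the atom-count-weighted mean of per-tail fractions.
- **Egress order** reports, per tail, the first frame whose per-tail
  fraction reaches `exit_threshold` (default 0.9 — "essentially fully
  out"), and the tails sorted by that frame. Ties break by tail index.

The head-tilt angle is measured between the PA→PB phosphorus vector and the
membrane normal (+Z by default). The direction PA→PB is a declared
convention (the literature rarely states one); a flag flips it, mapping
θ → 180° − θ. Frames where PA and PB coincide to < 1e-6 Å yield NaN rather
than an exception, and histograms (default bin width 2.5°, which places a
bin edge exactly at 112.5°) count finite angles only.

## Contacts and the geometric score

A residue is in contact in a frame iff any of its heavy atoms is within the
cutoff (default 4.0 Å, a common heavy-atom contact convention; always echoed
in output headers) of any lipid heavy atom — binary per frame, so the
per-replica frequency is a frame fraction in [0, 1]. Hydrogens are excluded
by the element field, falling back to name-based inference with a warning
when elements are absent. The implementation uses a KD-tree; the test oracle
is an O(N²) all-pairs scan.

The cross-replica score of a residue is the geometric mean of its
per-replica frequencies. This is deliberate: a contact observed in all but
one replica scores exactly zero, so the score measures *reproducible*
interaction, and by AM–GM it never exceeds the arithmetic mean. For a
single replica it is the identity. Scores map onto structures through the
B-factor column (range −9.99 to 999.99, two decimals), and residues missing
from a score table are written as 0.

## Synthetic data: what it emulates and what it does not

The generator builds a Cα-only barrel of `n_strands` strands (default 13)
on a cylinder of radius 15 Å, strands antiparallel, with one angular slot
left vacant — the lateral opening. Residue numbering starts at 424 with 19
residues per strand so that the default gate pairs (427/433/437 on the
first strand, 663/666/668 on the last) exist by construction. The
construction's gate plane is the least-squares plane of the base flank Cα
positions — the same plane the analysis recovers — so scheduled insertions
sit at a clean ±1.5 Å margin from it.

On top of the static geometry the generator realizes, exactly and
independently per stage:

- per-residue Gaussian positional noise (σ scalar or per-residue; default
  0.3 Å, giving aperture fluctuations well under 1 Å — the "stable gate"
  regime; RMSF recovery uses σ = 0.5 Å);
- a surrogate lipid head (PA/PB phosphorus pseudo-atoms 9 Å apart) whose
  tilt follows the prescribed schedule frame-exactly;
- six tail pseudo-atom chains whose per-frame inserted-atom counts equal
  the prescribed egress schedule (atoms sit at ±1.5 Å of the gate plane);
- probe atoms that sit 3.0 Å from their target residue's Cα in exactly the
  prescribed fraction of frames and 40 Å away otherwise, plus one decoy
  hydrogen parked 2.5 Å from a mid-barrel residue to exercise heavy-atom
  filtering;
- four membrane pseudo-atoms 2 Å outside the gate plane (so flicker depth
  is exactly zero unless a test moves them);
- optional explicit gate-pair distance schedules (the second residue slides
  along the pair's base direction).

Residues carrying a contact schedule (and their immediate strand
neighbours) and gate-pair residues under a distance schedule are *pinned* —
excluded from noise — so the schedules are realized exactly rather than
within a noise tolerance. Randomness is scoped per (seed, replica, stage),
so identical specs give bit-identical trajectories and adding a stage never
perturbs another's stream.

What the toy does **not** emulate: force fields, membrane thermodynamics,
water, correlated collective motions, realistic lipid geometry, or any
free-energy barrier to egress. Passing tests therefore demonstrate that the
*measurement* machinery is correct and deterministic — that a schedule a
trajectory actually contains is recovered exactly — not that any physical
system behaves this way. Real microsecond membrane simulations (≈10⁵–10⁶
atoms) remain the intended production input via the same PDB trajectory
contract or binary-format adapters.

## Pipeline, configuration, determinism

The CLI (`synth`, `analyze`, `aggregate`, `config init`) is a thin shell:
every number in every output comes from a library operation. Configuration
is YAML with all thresholds defaulted and printable via `config init`;
paths resolve relative to the config file. Output CSVs carry a header with
a hash of the analysis parameters (paths excluded) and the active cutoffs.
Aggregation truncates unequal replica lengths to the shortest with a
warning, refuses mixed gate definitions, averages aperture curves per
frame, and geometric-averages contact frequencies. Outputs use fixed
6-decimal formatting and no timestamps, so identical inputs give
byte-identical tables.

Problem sizes used by the test suite and the acceptance script — 13×19
residues, 40–5000 frames, 3 replicas — were chosen as the smallest systems
that exercise every code path while keeping Monte-Carlo recovery (RMSF
within 5% of σ√3) statistically comfortable.

## Known limitations

- PDB is the only full-fidelity format; XTC/DCD adapters are read-only
  hooks and mmCIF is not written. Insertion codes are rejected; first
  altloc wins.
- Contact bookkeeping is keyed by residue number only; multi-chain systems
  with duplicate numbering would need chain-qualified keys.
- The gate plane is one global plane; strongly curved or kinked gate mouths
  would need a piecewise definition.
- Secondary-structure assignment, PCA/clustering, hydration analysis and
  free-energy estimates are out of scope.
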