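# Methods

## Problem setting

Resistance–nodulation–division (RND) multidrug efflux pumps such as
*E. coli* AcrB and *K. pneumoniae* OqxB are homotrimers whose three
protomers cycle through loose (L), tight (T) and open (O) conformations
during transport ("functional rotation").  Single-particle cryo-EM can
resolve the state of each protomer: because the trimer is pseudo-C3
symmetric, each particle can be triplicated and rotated about the
three-fold axis so that all three protomers land in the same position
("symmetry expansion"), after which per-protomer classification yields one
state label per (particle, copy) pair.  The census question is then: given
those labels, what are the monomer-level state frequencies and the
trimer-level composition frequencies (LTO, TTO, TTT, …), and are the three
protomers of a trimer independent?  A fourth state, O*, has O-state
architecture but a closed exit channel; distinguishing it from O is a
geometric question about the exit-channel bottleneck radius, not an RMSD
question.

This package implements that pipeline on coordinates and labels.  It does
not process images or density maps: motion correction, CTF estimation and
2D/3D classification are upstream tools' business, consumed here as
coordinate models and label tables.

## Pipeline

1. **Axis estimation** (`symmetry.estimate_symmetry_axis`).  The axis
   direction is the rotation axis of the least-squares proper rotation
   (Kabsch) mapping chain 0 onto chain 1 over shared Cα atoms; the axis
   point is the centroid of the three chain centroids.  The axis from a
   chain-pair rotation is robust for hetero-conformer (e.g. LTO) trimers,
   where an inertia-tensor axis is not.  The sign convention is fixed:
   chain 0 → chain 1 is a counter-clockwise rotation viewed down the +axis.
   If the chain-pair rotation angle deviates from 120° by more than 15°
   (configurable) a pseudo-symmetry-violation warning is attached.

2. **Symmetry expansion** (`symmetry.symmetry_expand`).  Chain *k* is
   rotated by −k·120° about the axis; outputs are tagged (particle_id,
   copy_index).  For an exactly symmetric trimer the three expanded
   monomers coincide; for a trimer with i.i.d. Gaussian coordinate noise σ
   the expected pairwise RMSD between expanded copies is σ·√6 (each
   coordinate difference has variance 2σ², three coordinates per atom) —
   a property the tests verify by simulation.

3. **State assignment** (`states.StateAssigner`).  Each monomer is
   superposed onto every reference protomer over the *core* anchor (the
   transmembrane domain) and scored by porter-domain Cα RMSD; the states
   differ by rigid-body positions of the porter subdomains PN1/PN2/PC1/PC2,
   so restricting the statistic to the porter domain concentrates the
   signal that whole-chain RMSD dilutes (whole-chain is available via
   configuration).  The winner is the arg-min; numerical ties (within
   1e-9 Å) break by the fixed precedence L < T < O < O*, and a `tie` flag
   is raised whenever the runner-up is within 0.05 Å.  Monomers sharing
   less than 50% of a reference's core atoms are UNASSIGNED with a reason.

   **O\* override.**  If the winner has O architecture and the library
   contains an O* reference, the exit channel is probed: the channel module
   runs from the centroid of the scheme's exit-seed residues to the
   exterior, and the monomer is relabelled O* when the bottleneck radius
   falls below 1.5 Å (default; the closed-channel bottleneck range reported
   for OqxB is 1.1–1.5 Å) or when no path exists.  L/T winners are never
   O*-checked: O* is defined as an O-architecture state.

4. **Census** (`census.aggregate_census`).  Particles with exactly three
   assigned monomers form compositions (canonical name: labels sorted
   L < T < O < O*, so "OTT" and "TTO" are one key); incomplete or partially
   unassigned particles are dropped and reported, not imputed — how the
   original analysis treated trimers with monomers in rejected classes is
   not recorded, and dropping is the conservative, visible choice.  Monomer
   frequencies are computed from the same complete particles, which
   enforces the exact identity f_s = Σ_c p(c)·n_s(c)/3 structurally.

   *Uncertainty*: a particle-level nonparametric bootstrap (particles
   resampled whole, preserving intra-trimer correlation) with percentile
   95% intervals.  *Independence*: a G-test of the observed composition
   counts against the multinomial null P(c) = (3!/Π n_s!)·Π f_s^{n_s} with
   f̂ the observed monomer frequencies; categories with expected count < 1
   are pooled into one, and dof = (#categories after pooling) − (#states
   with nonzero frequency).  The null calibration of this test was checked
   by simulation (300 seeded null datasets of 5,000 particles: 1.0% of
   p-values below 0.01; KS test against uniform p = 0.85).

5. **Channels** (`channels`).  The clearance of a point is
   min over atoms of (‖x − atom‖ − r_vdw); the field is evaluated exactly
   on a regular grid (default spacing 0.8 Å, padding 6 Å; KD-trees per
   element accelerate but do not approximate).  Exterior nodes are those
   connected to the box boundary through nodes with clearance ≥ the probe
   radius (3 Å default).  A channel is the 26-connected path from a seed
   maximising the minimum clearance (widest path); ties prefer fewer
   nodes, then lexicographic order, so the search is fully deterministic.
   Nodes with clearance ≤ 0 are impassable; if the seed's positive-
   clearance component reaches no exterior node, the result is flagged
   `no-path` with the best achievable clearance reported.  This maximin
   objective shares bottleneck semantics with Voronoi-based tunnel tools
   (MOLE, CAVER) but is a deliberate simplification: path geometry and
   radius profiles away from the bottleneck will differ, and numerical
   agreement with those tools is not promised.  On grids ≤ 20³ the search
   is verified against an independent binary-search-over-thresholds +
   flood-fill oracle; engineered cylinder/cone fixtures recover their
   design radii within one grid spacing.

## Synthetic data: what it emulates, and what it does not

`synthetic.make_reference_library` builds abstract labelled point clouds —
one Cα pseudo-atom per residue, subdomain blobs (σ = 2.5 Å scatter) for
core, TM2, PN1, PN2, PC1, PC2 — rather than real protein geometry, so tests
never require downloads; real structures plug into the same interfaces.
States differ by rigid subdomain translations of 3–6 Å chosen so that
pairwise porter Cα RMSD between L/T/O templates is ≥ 2 Å (the package warns
when the requested coordinate noise would make states non-separable, i.e.
when porter RMSD < 4·σ√3).  O* equals O except for an engineered exit-pore
assembly: a sealed spherical shell with one tubular exit whose wall radius
sets the clear radius — 2.5 Å (open, O) or 1.2 Å (constricted, O*).  The
pore assembly is attached only when O* is among the requested states, since
it exists solely to give the O/O* discriminator something to measure.

`simulate_particles` draws a composition per particle from the given
distribution, deals its three states to copy indices uniformly at random,
places the templates at 0°/120°/240° about a common axis, applies a random
global rigid transform, and adds i.i.d. Gaussian coordinate noise.  All
generators are pure functions of (spec, seed).

What this does **not** emulate: image formation, classification error
structure beyond an i.i.d. confusion matrix (`corrupt_labels`), preferred
orientation, flexible (non-rigid) subdomain motion, and real side-chain
chemistry.  Passing tests therefore demonstrate that the census arithmetic,
the extraction geometry and the classifier logic are correct — not that
3D classification of real micrographs would achieve any particular
accuracy.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| grid spacing | 0.8 | Å | resolves a 1.1–1.5 Å bottleneck scale at tolerable cost |
| grid padding | 6.0 | Å | bulk solvent on all sides |
| probe radius (exterior) | 3.0 | Å | larger than any pore of interest |
| O* bottleneck threshold | 1.5 | Å | upper end of the reported closed-channel range |
| pseudo-symmetry tolerance | 15 | ° | flags non-trimeric/broken particles |
| tie margin | 0.05 | Å | flags unreliable calls without changing them |
| min core coverage | 50 | % | below this, UNASSIGNED |
| vdW radii | Bondi-style table | Å | shipped as `data/vdw_radii.tsv`; unknown elements fall back to 1.70 Å with a warning |
| subdomain schemes | `data/acrb_scheme.yaml`, `data/oqxb_scheme.yaml` | — | curated approximations, editable; **not** ground truth |

Simulation sizes used by the test suite and the reproduction script —
10,000 particles for frequency-recovery runs (multinomial SE ≈ 0.5
percentage points on a 50% composition), 100–300 particles for closure and
bootstrap checks, 300 replicates for calibration sweeps — were chosen so a
single-core run finishes in minutes while keeping statistical bounds
meaningful.

## Numerical choices

- Kabsch uses SVD with the determinant correction, so a reflection is never
  returned; orthogonality/unit-norm invariants are enforced at 1e-9.
- Rotation angles are extracted with atan2 of (‖antisymmetric part‖/2,
  (trace−1)/2) with the cosine clamped to [−1, 1]: accurate near 0° where
  plain arccos loses half the significant digits.
- Altloc resolution keeps the highest-occupancy conformer, ties broken by
  altloc identifier, giving a deterministic single-conformer model.
- Residue numbering follows the author numbering in the file (gaps
  preserved, no renumbering) because positions are cited by author numbers
  (V612, K946).  Hydrogens are ignored in all geometry.
- Composition-frequency inputs that do not sum to 1 (within 1e-6) are
  refused rather than silently renormalised.
- MIC calling on non-monotone OD series requires no-growth at the candidate
  *and every higher* concentration (the conservative reading of "lowest
  concentration with no growth"); out-of-range MICs propagate through
  wildtype ratios as censored inequalities, never as numbers.

## Known limitations

- The classifier is coordinate-space: it substitutes for, and cannot
  reproduce, map-space 3D class curation.
- The channel search reports one widest channel per seed; it does not
  enumerate or cluster channels, and its profiles are grid polylines.
- Whether a published O assignment would be O or O* under the bottleneck
  criterion depends on channel parameters the original analysis did not
  record; the assigner therefore reports both the label and the measured
  bottleneck so users can re-threshold.
- The chain naming of reference protomers in deposited models is not
  standardised; state-to-chain mappings must be supplied by the user.
- Shipped subdomain residue ranges are curation, not ground truth.
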