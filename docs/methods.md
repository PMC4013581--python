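# Methods

## The model

The simulator replaces an all-atom solvated force field with a vacuum
coarse-grained dual-basin structure-based model. Each residue is one
bead at the Cα position with mass 110 Da (the average residue mass).
Given two index-matched reference conformations ("open" and "closed"),
each basin *b* contributes

    V_b = Σ_bonds  k_b (r − r_b⁰)²
        + Σ_contacts(b)  k_c [(r − r_c⁰)² − (r_cut − r_c⁰)²]   for r < r_cut
        + Σ_non-native  k_rep (σ − r)²                          for r < σ

and the total potential is the log-sum-exp soft minimum

    V = −(1/β_mix) ln[exp(−β_mix V_open) + exp(−β_mix V_closed)].

Bonded terms cover (i, i+1) chain bonds and (i, i+2) pseudo-bonds (the
latter stand in for angle terms), each with per-basin equilibrium
lengths. Native contacts are pairs |i−j| ≥ 3 within the contact cutoff
in that basin's reference.

Two design choices deserve explanation:

* **Finite-depth contacts.** The contact wells are harmonic in
  (r − r⁰) but truncated flat at the cutoff and shifted so they reach
  zero there, giving each contact a finite depth k_c·(r_cut − r⁰)².
  Unbounded harmonic contacts would make any two-state transition
  impossible: separating a pair costs quadratically without limit, so no
  per-atom bias of realistic magnitude could ever detach the starting
  basin. With finite wells the breaking cost is bounded (a fraction of a
  kcal/mol to a few kcal/mol per contact) and the biased transition
  proceeds. The truncation leaves a force (not energy) discontinuity at
  the cutoff; near a basin minimum no pair sits at the cutoff, so energy
  conservation tests are unaffected.
* **Soft-minimum mixing.** With log-sum-exp blending, each reference is
  a local minimum of the *total* potential up to the mixing offset
  (≤ ln2/β_mix, ≈ 13.9 kcal/mol at the default β_mix), and the crossover
  between basins is smooth, which the targeted-MD restraint can pull the
  system across.

### Default parameters

| parameter | value | units | why |
|---|---|---|---|
| bond_k | 100 | kcal/(mol·Å²) | stiff chain; ω·dt ≈ 0.28 at the default step, stable and fast |
| contact_k | 0.2 | kcal/(mol·Å²) | well depths 0.5–3 kcal/mol (≈ 1–5 k_BT at 300 K): basins are stable yet breakable under a 0.5 kcal/(mol·Å²) per-atom bias |
| contact_cutoff | 7.5 | Å | ~2 bond lengths: captures first- and second-shell neighbors of a Cα trace |
| excluded_radius σ | 4.0 | Å | just above the 3.8 Å bead spacing |
| repulsion_k | 10 | kcal/(mol·Å²) | soft-core: forbids overlap without trapping the transition |
| beta_mix | 0.05 | (kcal/mol)⁻¹ | basin weights are e^{−β·ΔV}; at typical inter-basin gaps (≥ 100 kcal/mol) cross-contamination is < e⁻⁵ |
| time step | 0.01 | ps | coarse-grained beads are heavy and the stiffest mode slow; checked at startup (ω·dt < 0.8 enforced) |
| coupling τ | 0.2 | ps | thermostat coupling; Langevin friction γ = 1/τ = 5 ps⁻¹ |

Dynamics use the BAOAB Langevin splitting: with γ = 0 it reduces exactly
to velocity Verlet, which is how the energy-conservation test runs. The
heating phase ramps the thermostat set-point linearly (default 0 → 300 K)
with a 25 kcal/(mol·Å²) positional restraint; equilibration and
production run unrestrained at the final temperature. Minimization is
steepest descent with backtracking (Armijo) line search under staged
positional restraints (default 100/75/50/25 then unrestrained).

## The targeted-MD restraint

E_TMD = ½·k·N·[RMSD(t) − RMSD0(t)]², with RMSD the best-fit
mass-weighted RMSD to the target over the restrained selection (all
beads by default — the coarse-grained "backbone"; on all-atom input the
N, CA, C, O selection plays that role). The gradient of the best-fit
RMSD at the superposition optimum is g_i = w_i (x_i − ŷ_i)/(RMSD·Σw):
the rotational and translational derivative terms vanish there, and the
gradient is clamped to zero below RMSD = 1e-6 Å, where the function is
not differentiable. RMSD0 starts at the *actual* initial RMSD (so the
run begins unstrained, E_TMD(0) = 0) and decays linearly to zero over
the production window, holding at zero afterwards.

The packaged toy schedule (`toy_tmd_protocol`) uses 250 ps of
production. The choice is a compromise: the tracking lag
|RMSD(t) − RMSD0(t)| has a drag component proportional to schedule
speed and a geometric component that does not shrink with slower
schedules — the relocating segment's real-space detour around the core
is longer than the straight-line RMSD decay implies, so mid-transition
the constrained optimum RMSD sits roughly 1 Å above a linear ramp. At
k = 0.5 kcal/(mol·Å²) the measured operating band of the lag on the toy
system is about 1.0–1.5 Å in both directions; the final RMSD lands well
under 2.0 Å, the convergence criterion used throughout. Final RMSD
decreases monotonically in k over the scanned set {0.2, 0.5, 0.8, 1.0}.

## The synthetic two-state toy

`make_two_state_toy` places n beads (default 60) on a solenoid with
exact 3.8 Å consecutive-bead chords and ≥ 4.5 Å between turns. The
closed conformer keeps the core and relocates the terminal segment (the
"β7/8 analog", n/5 beads) along a smooth break-out, around-the-core,
downward path re-spaced to exact 3.8 Å bonds. The seed sets the global
azimuthal phase only, so coordinates are deterministic in the seed while
bond lengths and clearances are exact by construction; both states are
verified clash-free (nonbonded clearance ≥ 4.0 Å) and the open↔closed
backbone RMSD is required to be ≥ 6 Å (measured: 9.64 Å at the
defaults). A segment table labels toy analogs of β1, αA, the β5-αC
loop, β6/4/5, αC and β7/8.

What the toy does *not* emulate: real secondary structure and
Ramachandran statistics, side chains, solvent, and the specific contact
topology of any real protein. Passing tests on the toy demonstrate the
*machinery* — restraint forces, schedule tracking, analysis identities —
not that a particular real transition follows this pathway.

The other generators are exact by construction: the planted-correlation
trajectory gives expected within-block |C| = A²/(A² + 3σ²) ≈ 0.84 at the
defaults (A = 1.2 Å, σ = 0.3 Å) over an uncorrelated background, and the
hydrogen-bond fixture satisfies the default criteria in exactly
round(target·n_frames/100) frames, with the satisfying frames a
seed-determined permutation.

## Analyses: conventions and numerical choices

* **RMSD** is mass-weighted by default (uniform weighting available);
  Kabsch superposition enforces a proper rotation (reflection branch
  corrected via the smallest singular value).
* **DCCM**: Δr_i(t) = r_i(t) − ⟨r_i⟩ after RMS-fitting every frame onto
  the mean structure (mean → fit → recompute mean, one iteration);
  `fit=False` skips the fitting and the flag is recorded in the result.
  Zero-variance sites yield masked (NaN + flagged) entries with a
  warning, never silent zeros. Note that at F frames the finite-sample
  level of spurious off-diagonal entries is ≈ 1/√(3F) per entry
  (≈ 0.04 at F = 200), and the maximum over thousands of pairs is
  several times that; the suite therefore checks that frame fitting adds
  nothing *beyond* this baseline rather than asserting an absolute
  bound no estimator could meet.
* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 3.5 Å AND
  donor–H···acceptor angle ≥ 120°, both configurable; hydrogens are
  associated to donors by a 1.25 Å bond-length search in the first
  frame; occupancies are rounded to one decimal. Both N–H···O and
  O···H–N row notations denote (donor, acceptor) with the donor being
  whichever residue carries the hydrogen.
* **Hydrophobic contacts**: strictly < 4.5 Å between carbon atoms; in
  coarse-grained mode every bead counts as a carbon, which shifts the
  semantics from atom–atom to residue–residue proximity (documented
  here deliberately).
* **Segment distances** are internal coordinates (no superposition).
* **Pockets**: grid flood fill. Voxels whose center keeps ≥ probe
  radius clearance from every atom surface admit a probe; those
  connected (26-connectivity) to the box boundary are bulk solvent; the
  enclosed remainder are cavities, ranked by volume. The box margin is
  3·(probe + max radius) so boundary flood fill always starts in bulk.
  Volume counts probe-center-admissible voxels; the probe-excluded
  "shell" between protein surface and admissible region is used for
  lining-residue assignment, not volume — this is what makes the
  hollow-shell fixture converge to the closed form
  (4/3)π(R − r_atom − r_probe)³. Note that sparse shells have genuinely
  larger cavities than the closed form (the probe-excluded envelope
  bulges outward between atoms): the measured volume of a 60-atom shell
  exceeds the formula by ≈ 16% while agreeing with direct Monte-Carlo
  integration of the same geometry to ≈ 0.3%; the packaged fixture
  therefore uses 200 atoms. Default radii: C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20 Å; coarse-grained beads use `bead_radius` (3.4 Å in
  the pipeline). This is a voxel method, not an alpha-complex:
  numbers from weighted-Delaunay tools are comparable in kind, not
  reproduced digit for digit, and surface *pockets* with open mouths
  (as opposed to enclosed cavities) are out of scope.
* **Segment network**: an edge between residues i ∈ A, j ∈ B exists
  when |C(i,j)| ≥ c (default c = 0.5, always recorded in the output);
  the segment-pair weight is the count of such edges and the mean |C|
  is reported alongside. |C| is used because strong anticorrelation is
  also communication; signed sub-networks are available. Path queries
  minimize hop count, breaking ties toward the larger bottleneck edge
  weight, then lexicographically.

## The pipeline

`run_pipeline` chains toy generation (or loading), minimization + CMD
equilibration of both end states, the k-scan (0.2/0.5/0.8/1.0 by
default) with `select_force_constant` picking the smallest k whose
final RMSD beats 2.0 Å, bidirectional TMD, intermediate extraction at
schedule fractions 0.35/0.65/0.95 (early/middle/late transition) with
short CMD re-equilibration, and all analyses. The "time-average
structure" of a re-equilibrated intermediate is the mean of
post-burn-in frames after superposition onto the final frame — plain
coordinate means distort geometry, so the convention is recorded in the
output metadata rather than asserted as canonical. Outputs live under
one directory keyed by a config hash; a manifest records every stage
seed (all derived from the global seed via a seed sequence); a
completed run with an unchanged config is a no-op on rerun, and fresh
reruns reproduce numeric tables byte for byte.

## Problem sizes

The packaged study conditions are a 60-residue toy, a 250 ps / 25 000
step TMD schedule, 20 ps equilibrations, and 5-seed repeats for the
k-scan statistics; pocket grids default to 0.5 Å spacing (0.8 Å for
coarse-grained beads in the pipeline). These sizes make every result in
the test suite and the acceptance script reproducible on a single CPU
in minutes while keeping all the qualitative features of the method —
two distinct basins, a genuine barrier, a schedule slow enough to
track.

## Known limitations

* No solvent, electrostatics, or all-atom energetics; constant-pressure
  equilibration has no meaning in a vacuum coarse-grained model and is
  intentionally absent. Bond constraints (SHAKE-style) are unnecessary
  without hydrogens.
* The tracking-lag band (~1–1.5 Å at k = 0.5 on the toy) is a property
  of driving a detour-shaped transition with a linear schedule; systems
  whose two states interconvert by near-straight-line paths track
  tighter.
* Pocket measurement reports enclosed cavities only; open-mouth surface
  pockets require mouth analysis, which is not implemented.
* PDB I/O covers the v3.3 ATOM/MODEL dialect with single-character
  chain IDs; mmCIF and binary trajectory formats are out of scope.
* The coarse-grained hydrogen-bond pathway requires fixtures or
  all-atom input — beads carry no hydrogens, so occupancy analysis on
  bead models is skipped by the pipeline.
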