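# Methods

## The DPD model

All beads (polymer and solvent) interact through the standard soft DPD
force triple within the cutoff `r_c` (minimum-image convention):

- conservative: `F_C = a_ij (1 − r/r_c) ê`
- dissipative: `F_D = −γ (1 − r/r_c)² (ê·v_ij) ê`
- random: `F_R = σ (1 − r/r_c) θ ê / √dt`, with `σ = √(2 γ kT)`
  (fluctuation–dissipation), `θ` a unit-variance symmetric random
  variate drawn fresh per pair per step.

Bonds — both backbone bonds and the restraint bonds created from
contacts — are harmonic, `U = (k/2)(r − l0)²`, evaluated on the raw
real-space bond vector (see *Periodicity conventions*). The restoring
force is truncated at extension `bond_max_stretch` (default 2 `r_c`):
beyond it the bond pulls at the constant force `k · bond_max_stretch`.
Near equilibrium bonds never reach the cap; it exists solely so that the
grossly overstretched restraints of a fresh reconstruction start inject
bounded momentum. Without it, a restraint spanning a large fraction of
the box can accelerate beads past the stability guard (displacement >
box/2 per step), which aborts the run.

Integration uses the modified velocity-Verlet scheme with velocity
prediction factor `λ = 0.65`; positions update with the full force,
the new force is evaluated at predicted velocities `v + λ dt f`, and
velocities finish with the trapezoidal average. Bead mass is 1.

### Units and parameters

Reduced DPD units: `r_c = 1` (length), `kT = 1` (energy), bead mass 1.

| parameter | default | meaning / rationale |
|---|---|---|
| `a_pp = a_ss` | 25 | like-species repulsion; soft enough for chain crossing |
| `a_ps` | 55 | polymer–solvent repulsion; excess Δa = 30 gives Flory–Huggins χ = 0.286·Δa = 8.58 at ρ = 3, a strongly poor solvent |
| `r_c` | 1.0 | interaction cutoff, the length unit |
| `bond_k` | 40 | bond stiffness |
| `bond_l0` | 0.5 | unperturbed bond length; 0.8 maximizes benchmark accuracy; ≤ 0.3 destroys phantomness |
| `γ` | 4.5 | dissipative friction (standard value) |
| `kT` | 1.0 | thermostat temperature |
| `dt` | 0.04 | integration step; soft potentials tolerate it, kinetic T stays within 2% of kT |
| `ρ` | 3 | bead number density; the χ mapping coefficient 0.286 is calibrated at this density, which is also why ρ = 3 is the only density accepted by `chi_from_repulsion` |
| `λ` | 0.65 | velocity-Verlet prediction factor |
| `bond_max_stretch` | 2.0 | bond-force cap (see above) |
| `θ` | uniform | uniform on [−√3, √3] (unit variance) for speed; Gaussian available via config |

Boxes are cubic and periodic with edge `(N_total/ρ)^(1/3)`; given a
polymer of `n` beads at volume fraction `c`, the edge is
`(n/(cρ))^(1/3)` and the box is filled with solvent beads up to density
ρ, so the polymer-bead fraction equals `c` exactly.

### Pairwise random numbers

The random force is generated by a counter-based hash keyed on
`(seed, step, i, j)` with `i < j` (splitmix-style 64-bit mixing). Both
endpoints of a pair therefore see the same variate regardless of the
order in which pairs are visited, forces remain exactly antisymmetric
(momentum is conserved to round-off), and trajectories are bit-for-bit
reproducible for a given seed — including across the cell-list and
brute-force evaluation paths, which are required to agree exactly and
are tested against an independent O(N²) reference.

### Neighbor search

Forces are evaluated with linked cells of edge ≥ `r_c`, rebuilt every
step (no Verlet skin): beads are counting-sorted by cell into contiguous
arrays and each cell is scanned against a 13-offset half stencil plus
itself. Small or thin systems (N < 64 or fewer than 3 cells per
dimension) fall back to the all-pairs loop.

### Periodicity conventions

Positions are never wrapped; periodicity enters only through the
minimum-image convention of the *non-bonded* forces (and the cell
binning, which uses `pos mod L`). Bonded forces act on raw real-space
vectors. This split is deliberate: if bonds also used minimum image, a
chain could "thread" periodic images — bonded neighbors sitting a full
box length apart at zero bond energy — producing structures that are
compact in the torus but unusable for real-space distance maps. With raw
bonds, chains stay contiguous in real space by construction, and a
collapsed globule is a genuine single droplet.

### Thermometry

Kinetic temperature is twice the mean kinetic energy per degree of
freedom with `3N − 3` degrees of freedom (total momentum is conserved
and removed at initialization). The integrator's built-in accumulator
averages it over the run; a pure-solvent box at the default parameters
holds `T = 1.00 ± 0.02` over 10⁴ steps, which the test suite checks.

## Gold standards

**Globule.** A chain is collapsed in the poor solvent (χ = 8.58) at 10%
polymer volume fraction. The initial conformation is a random walk
folded into a compact region at the box center (~1.7× the equilibrium
droplet volume): starting compact makes equilibration a matter of local
rearrangement instead of a slow collapse from a box-spanning coil, and
the equilibrium state is the same. The run stops when the radius of
gyration plateaus — relative spread < 1% over the trailing 20% of
elapsed steps, never before 10 checkpoints — within a budget of
2×10⁵ steps scaled by `n/4096`. A converged globule must also be a
single cluster (≥ 99% of beads in the largest `r_c`-linkage component).
Repulsion stretches bonds beyond `l0`: the equilibrium median backbone
bond length at `l0 = 0.5, k = 40` is ≈ 0.65, which the acceptance
script recomputes.

**Solutions.** Same protocol in an athermal solvent (`a_ps = a_pp`) at
the requested volume fraction; `c = 1` is a melt with no solvent. Coils
fluctuate strongly, so the plateau tolerance is looser (5%) and
benchmark points on solutions should be averaged over independent
replicates (the sweep runner takes a replicate count; replicate *i* uses
`base_seed + i`).

**Moore curve.** The deterministic reference: eight isometric copies of
the order-(n−1) 3D Hilbert curve (generated by the iterative transpose
algorithm) placed in the octants along a closed Gray-code cycle. The
per-octant isometries are found once by backtracking over the 48 cube
isometries under the adjacency constraints; the result is a closed
Hamiltonian cycle through all `8^order` sites of the `2^order` cube —
every consecutive pair (and the last–first pair) at lattice distance 1,
every site visited exactly once, verified exhaustively in the tests.
Coordinates are multiplied by a target bond length so the curve can be
used as a gold standard at any `l0`.

**Random walks.** Reconstruction starts and the low-density baseline:
fixed-step walks whose steps are redrawn whenever they would leave the
box, so bond lengths are exact and all coordinates lie inside the box.

## Contacts

A contact is any non-bonded pair at Euclidean distance ≤ `r_contact`
(inclusive). Backbone-adjacent pairs are excluded everywhere — they are
in contact by construction and would duplicate backbone bonds as
restraints. Genomic pairs records are binned by `floor(pos/resolution)`
with 0-based half-open coordinates, one chain per chromosome; intra-bin
and bin-adjacent (same-chromosome) contacts are dropped for the same
reason, duplicates collapse into multiplicities, and inter-chromosomal
contacts are kept by default (`trans="drop"` available). Sample counts
round half away from zero so subsample sizes are reproducible.

The diagonal-preserving shuffle redraws, for every separation `s`, the
same number of pairs uniformly among the `n − s` slots — the standard
randomized control that keeps the contact-frequency-vs-distance profile
while destroying positional information. It treats the map as one chain
(slots are not restricted to chain interiors), which is exact for
single-chain maps and a close approximation for genome-scale maps where
chains are long compared to typical separations.

## Comparison metric

Distance maps are all-pairs Euclidean matrices (no periodic wrapping —
conformations are compact, real-space structures); optional
normalization divides by the radius of gyration of the whole polymer,
making the comparison scale-free so structures from methods with
different spatial units can be compared. The Modified Jaccard Index is
`‖(D − D′)/2‖ / ‖(D + D′)/2‖`; entries missing in either map's mask
(e.g. failed imaging probes) are excluded from both norms. IMJ is 0 iff
the maps are equal and invariant under rigid motion and reflection of
either conformation.

The random baseline uses symmetric matrices with iid uniform [0, 1]
off-diagonal entries: for that ensemble the IMJ converges to
`√(E[(X−Y)²]/E[(X+Y)²]) = √(1/7) ≈ 0.37796`, matching the quoted 0.378
and stable in matrix size. The uniform-entry choice is an inference —
any symmetric iid ensemble could serve as "random" — adopted because it
reproduces the printed constant analytically. Accuracy is the linear
rescaling `(IMJ_r − IMJ)/IMJ_r · 100%`; values below 0 (worse than
random) are reported, not clipped. Two *unrelated* globules score well
above 0% (≈ the model's x→0 intercept of 33.5%) because any two compact
droplets share gross features; this is the floor against which
reconstructions should be judged, and the accuracy model's `1 − A`
offset encodes it.

## Reconstruction

`build_restrained_system` starts each chain as an in-box random walk,
fills with solvent, and adds one restraint bond per contact with the
same `(k, l0)` as the backbone — no per-restraint weighting, matching
the equal treatment of the two bond populations. Most restraints start
overstretched (> 50% beyond `2 l0` for dense maps; the force cap keeps
this integrable). Poor solvent is the default regime (globular targets,
appropriate for chromatin at coarse resolution); good solvent is
available for coil-like targets. Default concentration is 10%,
a nuclear-chromatin-like volume fraction, config-exposed.

Equilibration runs in chunks and stops when the median restraint-bond
length is stationary (relative change < 1% over the trailing 20% of
steps, checked at ~5% budget intervals, never before 10 checkpoints)
within a budget of 10⁵ steps per 512 beads scaled linearly; exhausting
the budget returns `converged=False` rather than an error. `l0 ≤ 0.3`
is rejected unless explicitly overridden, because the chain then loses
phantomness and the reconstruction can trap topologically; the test
suite demonstrates the underlying physics directly with two linked
rings of fixed geometry that unlink thermally at `l0 = 0.5` but mostly
stay linked at `l0 = 0.2`. The final conformation is solvent-stripped
and re-centered, with backbone and restraint bond-length samples and
the restraint-satisfaction fraction (lengths ≤ `r_c`) attached.

## Benchmark sweeps and problem sizes

`run_radius_sweep` varies the contact radius (keeping the closest,
structure-defining contacts); `run_dropout_sweep` retains a random
fraction of the full map (modeling stochastic dropout) and optionally
fits the exponential accuracy model to the pooled points. At equal
contacts per bead, radius reduction degrades accuracy more gently than
dropout.

Default working sizes in tests and the acceptance script are
desk-scale: 512-bead gold standards (the smallest Moore order with a
non-trivial interior is 8³ = 512), reconstruction budgets of ~10⁴ steps
at that size, 3–5 seeds per point. These sizes resolve the qualitative
relations (monotone accuracy in contact density, bond-statistics
equilibration, the accuracy ceiling) with runs of seconds to a few
minutes each; publication-grade curves at N = 4096 with full sweep
grids use the same code paths with larger `ExperimentSpec` settings.

## Synthetic data

`make_fixture` emulates single-cell-like inputs: contact lists with
power-law contact-probability decay `P(s) ∝ s^decay` (default −1) and a
target contacts-per-bead density in the experimentally observed
0.001–1 range, either as genomic pairs records or as a binned map, and
imaging-style dense distance maps with whole rows/columns missing. What
it does *not* emulate: genomic artefacts (unmappable bins, repeats),
chromosome-territory structure, trans-contact enrichment, or distance-
dependent false positives of proximity ligation. Tests passing on these
fixtures therefore validate the machinery (binning, sampling, masking,
reconstruction plumbing), not biological fidelity on real data.

## Numerical choices and degenerate inputs

- Inclusive contact threshold (`≤ r_contact`); contacts at exactly the
  radius are kept.
- Sample counts round half away from zero.
- The accuracy-model fit is bounded (0 ≤ A ≤ 1, β > 0,
  0 < A_max ≤ 100) and needs ≥ 4 points; noiseless model points are
  recovered to 10⁻⁶.
- Degenerate systems: a two-bead map is trivially converged; an empty
  contact map reconstructs an unrestrained (uninformed) chain; an
  all-constant contact map makes the Spearman similarity undefined and
  is signalled as an error.
- A bead displacement exceeding half the box edge in one step aborts
  integration with an explicit error; non-finite coordinates fail fast
  naming the offending bead.

## Known limitations

- The χ mapping supports ρ = 3 only; other densities would need their
  own calibration coefficient.
- Collapse of a long chain from a fully extended box-spanning start is
  deliberately avoided (compact initialization); if such a protocol is
  required, budget for far longer runs.
- The shuffle control and genome binning treat chromosome copies as
  single chains; haplotype-resolved reconstruction is out of scope.
- No balancing/normalization of bulk Hi-C matrices and no read-level
  artefact filtering: inputs are assumed to be cleaned contact lists.
- Accuracy values on very sparse 0/1 contact-map comparisons (as
  opposed to distance-map comparisons) are routinely negative; only
  their ordering against controls is meaningful there.
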