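# Methods

## Model

`dpdsolvex` simulates the solvent-exchange ("dialysis") self-assembly of a
short-corona amphiphilic diblock copolymer with dissipative particle
dynamics (DPD).  Four coarse-grained bead species live in a periodic cubic
box at reduced number density ρ = 3: W, a selective solvent good for the
hydrophilic block only (water-like); G, a cosolvent good for both blocks;
and the copolymer blocks A (hydrophilic) and B (hydrophobic).  The model
chain is A₂B₁₂ — a weak hydrophilic fraction (14 %) that favours vesicles
and liquid–liquid phase-separated (LLPS) precursors over classical
micellization.

The force on bead *i* is the pairwise sum, inside a cutoff r_cut = 1, of

* a soft conservative repulsion  F^C = a_ij (1 − r/r_cut) r̂,
* a dissipative drag             F^D = −γ w_D(r) (r̂·v_ij) r̂,
* a stochastic impulse           F^R = σ w_R(r) ξ_ij Δt^(−1/2) r̂,

plus a harmonic spring F^S = C^S r_ij (zero equilibrium length) between
bonded beads.  Reduced units m = r_cut = k_BT = 1 throughout.

Repulsion amplitudes map linearly to the Flory–Huggins parameter at ρ = 3,
χ_ij = 0.286 (a_ij − a_ii) with a_ii = 25.  The working matrix is

|     | W  | G      | A  | B  |
|-----|----|--------|----|----|
| W   | 25 |        |    |    |
| G   | a_WG | 25   |    |    |
| A   | 25 | 25     | 25 |    |
| B   | 50 | 25     | 50 | 25 |

with a_WG the single free knob: 15 (χ = −2.86) models a strongly attractive
water/cosolvent pair (e.g. DMSO/water), 30 (χ = 1.43, below the monomer
demixing point χ_crit = 2) a marginally miscible one (e.g. THF/water).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| γ (drag) | 4.5 | reduced | standard DPD friction; sets viscosity |
| σ (noise) | √(2γk_BT) = 3.0 | reduced | fluctuation–dissipation; not an independent knob |
| w_R, w_D | 1 − r, (1 − r)² | — | standard weight-function pair consistent with the thermostat |
| C^S (spring) | 4.0 | force/length | chain connectivity stiffness |
| Δt | 0.05 τ | reduced time | soft potentials tolerate it; kinetic temperature stays within 2 % of 1 |
| λ (integrator) | 0.65 | — | modified velocity-Verlet velocity-prediction factor |
| ρ | 3 | beads/r_cut³ | the density at which the χ mapping slope 0.286 holds |

The integrator is the modified velocity-Verlet scheme: the dissipative
force of the new step is evaluated with velocities predicted as
v + λΔt f.  λ and the weight functions are package choices — only the
parameter values γ = 4.5, C^S = 4.0, Δt = 0.05 are fixed by the study
conditions; the functional forms are the standard ones the DPD literature
attaches to them.

### Stochastic force and determinism

The pair noise ξ_ij is produced by a counter-based hash RNG keyed on
(seed, step, i, j) (splitmix64 mixing + Box–Muller).  Consequences worth
knowing: F^R_ij = −F^R_ji holds exactly, so the thermostat conserves
momentum to floating-point accumulation; the cell-list and all-pairs force
paths are bitwise identical (pairs are accumulated in sorted (i, j) order
in both); and a checkpoint (positions, velocities, species, cached forces,
step counter) restarts a trajectory bit-for-bit.

## Scenario construction

A scenario is a box (default edge 60, i.e. 6.48 × 10⁵ beads), a chain count
(default 1000, copolymer volume fraction ≈ 2.16 %), and an initial solvent
composition ϕ_W^init = n_W/(n_W + n_G) × 100 (default 30 %).  Chains are
placed as unit-step random walks (soft potentials permit overlap), solvent
uniformly; the W count is floor(ϕ_W^init/100 × n_solvent).  Velocities are
Maxwellian with zero total momentum, rescaled to kinetic temperature 1.
Preparation runs in two stages: 10⁵ steps with every a_ij = 25 (athermal
homogenization), then the working matrix is switched on — positions are
untouched at the switch — followed by 2 × 10⁶ equilibration steps at full
scale (both stage lengths are configurable and are scaled down in tests).

## Solvent exchange

Each exchange round relabels G beads to W:

1. count the *eligible* G beads n_G,out — those farther than the
   eligibility distance (default 1.0 r_cut, the same contact radius the
   solvation metrics use) from every copolymer bead;
2. the exchanged count is n_G,sup (default 1.25 % of all solvent beads)
   when n_G,out > 2 n_G,sup, else floor(0.5 n_G,out);
3. that many eligible beads, sampled uniformly without replacement from a
   dedicated RNG stream, change species; positions, velocities and bonds
   are untouched, and velocities are not re-thermalized (identity swap
   only);
4. the system equilibrates for t_eq steps (default 2 × 10⁵; a slow mode of
   6 × 10⁵ suits the weakly repulsive cosolvent whose clusters coalesce
   slowly).

The loop ends once fewer than 200 G beads remain (threshold scaled
proportionally to the solvent count in reduced boxes, floor 2), and the
trace cosolvent is relabelled in one final sweep.  A stagnation guard
aborts with a diagnostic if the quota is zero for (default) 10 consecutive
rounds — reachable in very small boxes where floor(0.5 n_G,out) can park
at zero near termination; raising the termination threshold is the
intended remedy at toy scale.

## Morphology analysis

*Clusters.*  Two chains aggregate when any of their hydrophobic (B) beads
lie closer than 1.5 r_cut (strict inequality, minimum image).  Components
of the B-contact graph are lifted to whole chains; hydrophilic contacts
never merge clusters.  Cluster size n_agg counts chains.

*Unwrapping.*  Before any shape analysis a cluster is made contiguous by a
BFS over its connectivity graph (bonds plus B-contact edges), placing each
bead at the minimum-image position relative to its parent.  This assumes
the aggregate spans less than half the box — true at every scale used
here, but a limitation for percolating structures.

*Shape.*  The gyration tensor S_ab = (1/n) Σ (a_i − ā)(b_i − b̄) has sorted
eigenvalues λ₁ ≤ λ₂ ≤ λ₃, ratios r31, r32, r21 and R_g² = λ₁+λ₂+λ₃.
Labels: *spheroidal* when r31 ≤ 1.5; otherwise *flat-cylindrical* when
r21 ≥ 1.25 (the flattened ribbon/disk family) or *elongated* (prolate).
Degenerate sets (n < 2 or λ₁ = 0) carry an infinity flag.

*Density profiles.*  Number densities of all four species either in
spherical shells around the cluster centre of mass, or in slabs along the
λ₃ eigenvector restricted to a cylinder of configurable radius (default
3 r_cut) so slab volumes are well defined.

*Cavities.*  A lattice (spacing 0.5 r_cut) over the unwrapped cluster is
marked occupied within 0.75 r_cut of any B bead; free cells are
flood-filled from the boundary (6-connectivity) and any enclosed region of
at least 1.0 r_cut³ (about one bead's share of space at ρ = 3; smaller
voids are packing noise) is a cavity, reported with its volume and
enclosed W/G counts.

*Aggregate labels.*  A rule combines the signals: any closed cavity ⇒
*vesicle* (spheroidal) or *semi-vesicle* (anisotropic); else a
flat-cylindrical shape ⇒ *disk*; else a well-mixed, solvent-rich interior
(|segregation index| < 0.15 and interior solvent fraction > 0.35) ⇒
*LLPS-like*; an inward-drawn corona (segregation < −0.15) ⇒
*semi-vesicle*; remainder ⇒ *micelle*.  The segregation index is the
radial centroid of A minus that of B, normalized by R_g; the interior is
the ball holding 80 % of the polymer beads.  Thresholds were calibrated on
the synthetic fixtures (hollow shell, punched shell, oblate disk,
interleaved blob, solid sphere with corona), each of which the classifier
must label correctly by construction.  Because instantaneous eigenvalue
ratios of small aggregates fluctuate strongly, the terminal structure of a
run is judged by a consensus report: tail-averaged eigenvalues,
segregation and solvent-fraction signals with the median cavity count,
passed through the same rule.

## Solvation metrics

A solvent bead *contacts* the polymer at distance ≤ 1.0 r_cut (inclusive —
deliberately different from the strict < 1.5 cluster criterion; both
constants are centralized).  Reported per composition: the contacting
fraction of all solvent beads; the G share among them (enrichment above
the bulk ϕ_G = 100 − ϕ_W signals preferential adsorption); n_WA, the
number of W beads touching the A block (its minimum against ϕ_W is the
cononsolvency signature); and the mean A–A bond length (the A–B junction
bond is excluded by default, switchable).  Frame averaging over an
equilibrated tail window is left to the caller.

## Numerical choices and degenerate inputs

* Exact pair overlap (r = 0): zero force, counted, never an exception.
* Non-finite coordinates or velocities abort the step with a diagnostic
  before they can corrupt the neighbour grid.
* Cell lists are rebuilt every step (cell edge ≥ r_cut, half-shell
  enumeration); boxes under 3 cells per edge fall back to the O(n²) scan.
* floor() everywhere a fractional bead count appears (solvent split,
  exchange quota): bead counts are integers and the conservative choice.
* Empty profile bins report density 0; clusters with fewer than 30 beads
  or degenerate tensors are labelled "degenerate", not classified.

## Equation-of-state reference

The pure fluid at ρ = 3, a = 25 is checked against an independent
Metropolis Monte Carlo sampler of the same conservative potential
(tests/mc_reference.py), which gives P = 23.66 (excess coefficient
α = 0.0918).  The DPD engine reproduces this within statistical error and
independent of Δt.  The widely quoted quadratic fit
P = ρk_BT + 0.101 a ρ² overestimates the exact ensemble value by ≈ 8 % at
this state point, so the MC number — not the fit — is the test reference.

## Scaled problem sizes, and what the tests do and do not show

The full-scale study conditions (60³ box, 6.48 × 10⁵ beads, 2 × 10⁶-step
stages, five replicates) are far beyond a single-CPU test run; the suite
exercises the same physics at reduced sizes chosen once:

* engine/thermostat checks: 6³ box (648 beads), 10⁵ steps;
* dialysis protocol checks: 6³ box, 4 chains, short t_eq;
* pure-water self-assembly: the scaled profile 15³ box (10,125 beads),
  50 chains, ~4 × 10⁴ steps;
* cosolvent-comparison segments: 10³ box (3,000 beads), 16 chains,
  matched seeds, six exchange rounds at t_eq = 1500.

At these sizes the *direction* of every effect is reproducible — chains
aggregate irreversibly in pure water; the weakly repulsive cosolvent
(a_WG = 30) is more enriched in the polymer contact shell and keeps more
solvent in contact than the attractive one (a_WG = 15).  What the scaled
runs cannot show is the large-aggregate pathway morphology itself: a
50-chain aggregate (the full-scale disk and vesicle intermediates hold
~400–500 chains) is small enough that surface tension keeps it compact, and its
tail-consensus label is "micelle" (tail-averaged r31 ≈ 1.5) rather than a
bilayer-family structure.  The corresponding pathway assertion in the
acceptance suite is therefore expected to fail at this scale; it is kept
faithful rather than loosened.

## Known limitations

* No electrostatics, angle/dihedral terms, or pressure coupling.
* Cluster unwrapping assumes non-percolating aggregates.
* The synthetic fixtures emulate geometry (shells, disks, blobs), not
  equilibrium DPD statistics: classifier calibration on them validates the
  decision rule, not the thermodynamics of real aggregates.
* XYZ trajectories carry no bond information; analysis of a trajectory
  file treats polymer beads as single-bead chains, which preserves bead
  counts and shapes but not chain-resolved n_agg.
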