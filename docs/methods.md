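# Methods

## Scope and data model

All analyses operate on membrane-plane (2D) trajectories: particle
records (receptors A2A/D2, phospholipids, cholesterol) with lateral
coordinates in a rectangular periodic box, times in μs, lengths in nm,
angles in rad. Every inter-particle distance is a *lateral*
minimum-image distance; receptor positions are treated as centre-of-
mass points. Trajectories load from a self-describing text fixture
format (bit-exact round trip via float repr) or from GRO+XTC / PDB+DCD
through MDAnalysis, with residues collapsed to lateral COMs and
Å → nm, ps → μs conversion.

Periodic geometry: displacement components are mapped to (−L/2, L/2];
unwrapping accumulates minimum-image steps (particles moving ≥ L/2
between frames are flagged unreliable); the periodic centre of mass
uses a circular-mean seed followed by an exact linear average of
minimum-image offsets, so compact clusters reproduce the recentred
naive COM to machine precision.

## Contact and oligomer analysis

Two receptors are in direct contact when their lateral COM distance is
strictly below the cutoff (default 4.2 nm). The criterion is
distance-only, so lipid-mediated contacts count; no persistence filter
is applied by default — the analysis window does that job. A cutoff of
at least half the shortest box edge is rejected as ambiguous under
periodic boundaries.

Aggregation is summarised as the mean number of contacts per protomer
over receptors and frames in a late window, by default the final third
of the run (generalising a last-20-of-60-μs convention). Errors are
SEM across replicas when ≥ 3 replicas exist, otherwise a 5-block SEM
within the run. Oligomers are connected components of the contact
graph (scipy csgraph; an independent networkx oracle checks this in
the tests). Condition comparisons report the relative difference of
windowed means and a two-sided Welch t test on per-replica means.

Coarse-grained times can be converted to effective time with the
standard ×4 friction factor; the conversion is applied only at
reporting, never to stored trajectories. The effective oligomerisation
onset radius is the contact cutoff plus twice the solvation-shell
width, e.g. 4.2 + 2×0.9 = 6.0 nm — the distance at which two
DHA-coated receptors begin to sense each other through their shells.

## Lipid environment

The 2D RDF normalises annulus counts by the ideal-gas expectation
ρ·π(r_out² − r_in²) per reference per frame, so g → 1 for uniform
targets (mass conservation Σ g·area·ρ equals the mean in-range count
exactly). Default bin width 0.05 nm; r_max capped at half the box.

Shell detection takes any RDF curve and returns the first local
minimum after the global maximum where g has fallen below 1 (the
excluded-core radius is the largest r below the peak with
g < 0.05·peak; width = outer − core). On the synthetic presets the
pooled all-lipid curve is nearly structureless — species peak at
different radii — so the packaged analyses detect the shell on the
DHA-lipid curve, which carries the actual first-shell structure.
Occupancy counts lipids within the outer radius of the nearest
receptor, per frame, over a caller-chosen species set; the headline
claim (the DHA phospholipid dominates the first shell) is evaluated
among phospholipids, since cholesterol is a third of all lipids and
its bulk abundance swamps any disc-based count.

Receptor–lipid contact ratios (e.g. unsaturated/saturated) use a
bead-scale cutoff, default 0.6 nm, normalised per available particle
of each class before the ratio; the demixing contact fraction uses a
lipid–lipid cutoff of 1.1 nm. Both cutoffs are package conventions
(the underlying experimental protocol does not print values) and are
exposed as parameters. f_AB is reported with its random-mixing
reference 2·x_A·x_B; frames with no lipid–lipid contact are flagged
undefined rather than silently dropped.

## Diffusion estimation

The MSD is time- and ensemble-averaged over all origins and selected
particles, lateral components only, and requires unwrapped input
(near-box-length jumps abort with instructions). D comes from weighted
least squares of MSD = 4DΔ + b with weights equal to the per-lag
sample counts and a free intercept that absorbs short-time artefacts.
The default fit window keeps lags within 10–50% of the maximum lag;
the exact protocol of the source analyses is not public, so this
package convention is fixed here and stated with every estimate. A
negative fitted slope reports D = 0 with a warning.

Rotational diffusion uses C(Δ) = ⟨cos(θ(t+Δ) − θ(t))⟩, which for a
free planar rotor is exactly exp(−Dr·Δ); Dr is the log-linear slope
over C ≥ 0.3 (below that, log-noise dominates). Replica aggregation is
an unweighted mean with SEM for n ≥ 3, propagated fit errors
otherwise. Units: diffusion is stored in nm²/μs and converted exactly
(1 nm²/μs = 10⁻⁸ cm²/s).

## Composition accounting

Composition tables are read as counts per 100 phospholipids, each
phospholipid contributing two fatty-acyl tails and cholesterol none,
so tail percentages use the nominal 200-tail denominator. Printed
columns summing to 101 instead of 100 are accepted within ±1; this
convention reproduces the published C16:0 and C22:6 fatty-acid rows
exactly (51% and 3% for the diseased column), which renormalising by
the actual 202-tail total would not. The C18:0/C18:1 rows of such
tables are not reproducible under any single sphingomyelin/oleoyl
convention, so only the convention-robust rows are relied on; SM is
counted as one C18:1 (sphingosine) plus one C16:0 (acyl) tail.
Integer-reported percentages round half away from zero (10.5 → 11).
Particle counts for the simulator are apportioned by largest
remainder with ties broken by species name, so counts always sum
exactly to the requested total.

Built-in presets: `healthy` (DPPC 21, DSPC 7, DOPC 15, SDPC 21, SM 36;
33% cholesterol; 10.5% DHA tails), `diseased` (33, 15, 11, 6, 36; 33%
cholesterol; 3.0%), and `ternary_high_dha` (POPC:SDPE:CHOL 30:50:20;
31.25%).

## Synthetic membrane generator

The generator is an overdamped (inertia-free) Euler–Maruyama scheme in
a periodic plane with kT ≡ 1:

    Δx = √(2DΔt)·N(0,1) + D·F·Δt,    Δθ = √(2DrΔt)·N(0,1)

Pair forces derive from a quadratic soft core inside r₀ (stiffness
k_rep = 25 + 20ε kT, so deep wells cannot compress pairs into the
core) plus a Gaussian attractive well −ε·exp(−(r−r₀)²/2σ²), truncated
and shifted to zero at r₀ + 3σ. Neighbour search uses a periodic
k-d tree per step. Identical (config, seed) gives bit-identical
output; random initial placements are relaxed by a short deterministic
soft-core-only descent so no saved frame starts from steric overlaps.
A stability guard refuses configurations with √(2DΔt) ≥ σ/5.

The study presets place 9 A2A + 9 D2 receptors and 400 lipids
(apportioned from the composition presets) in a 33 × 33 nm box — the
receptor density of a replicated 11 × 11 nm two-receptor patch — and
run 4 μs raw (16 μs effective) at Δt = 10⁻³ μs. These sizes keep a
full two-condition, multi-seed study in the minutes range on one CPU;
the dataclass default Δt is 10⁻⁴ μs for configurations with finer
wells. Generating diffusion coefficients are the measured values:
receptors 0.48/0.46 (healthy) vs 0.18/0.22 (diseased) nm²/μs, lipids
per the crowded-membrane table (e.g. SDPC 2.1 vs 1.3), ternary lipids
8.1/8.1/12.4. Rotational Dr uses the same numbers in rad²/μs — no
measured magnitudes exist, only the healthy > diseased ordering, which
this preserves.

Interactions encode the emergent statistics, not the underlying
force field: receptor–receptor binding wells (ε = 4 kT, r₀ = 4.0 nm)
make consolidated contacts effectively irreversible on the simulated
timescale; DHA-lipids are attracted to receptors (solvation shell,
r₀ = 2.2 nm) and to each other (ε = 1.5 kT, driving partial
demixing); all other pairs are excluded volume, with non-DHA lipids
held slightly further from the receptor surface (r₀ = 3.1 nm) to
encode the entropic preference of flexible DHA chains for the protein
interface. The shell well is deeper in the DHA-poor condition (3.5 vs
2.5 kT): with no DHA-rich bulk domains to partition into, the receptor
surface is the only favourable environment for the scarce DHA lipid —
this is what keeps practically all of it receptor-bound there, while
the DHA-rich membrane retains a freely diffusing fraction. Presets are
calibrated to reproduce orderings (healthy aggregates faster; bound
DHA fraction higher when DHA is scarce; demixing increases with
like-like attraction), not absolute magnitudes — no association-rate
constants exist to match.

What the generator does *not* emulate: coarse-grained bead structure
and internal protein degrees of freedom, leaflets and membrane
undulations, hydrodynamic coupling, and genuine binding/unbinding
equilibria. Passing tests therefore validate the estimators and the
qualitative DHA physics, not force-field-level quantities.

## BRET analysis

BRET ratio: 1000·(F − F_bg)/(L − L_bg) in mBU. The saturation model is
BRETmax·x/(BRET50 + x) with x the acceptor expression proxy
(acceptor/donor normalisation is configurable; the exact abscissa of
the source assay is not stated). Fitting is bounded nonlinear least
squares with multistart; non-convergence falls back to the linear
bystander model, flagged. Model selection runs an extra-sum-of-squares
F test of the 2-parameter hyperbola against the 1-parameter
proportional model at α = 0.05 — the formal counterpart of judging
saturation by eye. Condition comparisons use the paired two-sided t
test across experiments with a zero-variance convention (identical
pairs → t = 0, p = 1). The titration generator produces hyperbolic or
bystander plates with multiplicative Gaussian noise in triplicate
wells, deterministic per seed.

## Statistical conventions and problem sizes

- Analysis windows are half-open [t_start, t_end); frames index from 0.
- Estimator-recovery experiments use 500 free walks × 10 seeds, frames
  every 10⁻³ μs, MSD fit over 10–100 ns lags; recovery is asserted
  within 2 SEM over seeds (a ~t₉ criterion, so occasional near-misses
  are expected behaviour, not defects).
- The paired-t type-I property is measured over 4000 seeded null
  repeats: at 1000 the binomial noise of the rate estimate (±0.7%) is
  comparable to the width of the 4–6% acceptance band itself.
- Condition-ordering properties are asserted over 5 seed pairings
  (≥ 4/5 wins), matching the replica count a desk-scale study affords.

## Known limitations

- The generator's absolute contact counts (~0.5/protomer at 16 μs
  effective) sit below the long-run coarse-grained values (~1.2–1.5 at
  60 μs); only orderings and estimator behaviour transfer.
- Shell detection assumes a peaked RDF; broad multi-species plateaus
  return "undetectable" rather than guessing.
- MD-format input collapses residues to points; no per-bead contact
  analysis is offered for atomistic data beyond the contact-ratio
  machinery on generic particles.
- The fixture format stores one orientation angle per receptor; 3D
  rotational diffusion is out of scope.
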