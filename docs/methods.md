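# Methods

## Scope and units

`confdyn` implements the analysis layer of a two-state conformational
study of a nuclear-receptor ligand-binding domain (LBD): collective
variables, biased-sampling free-energy machinery, and trajectory
statistics. Production all-atom molecular dynamics is out of scope; the
package verifies its machinery on low-dimensional toy systems with
analytic ground truth and on synthetic structures built to have known CV
values.

Internal units are nm, kJ/mol, ps and K throughout, with
kB = 0.0083144621 kJ·mol⁻¹·K⁻¹ and a default temperature of 300 K. PDB
files (Å) are converted at the I/O boundary only. Residue numbering is
the author (PDB) numbering used verbatim — the receptor recipes refer to
residues 683–933 — with no internal renumbering.

## Structures and selections

A `Structure` is an ordered atom list indexed by
(chain, residue number, atom name); the index must be unique, and
read→write→read round trips preserve atom order and coordinates at PDB
precision (10⁻⁴ nm). Reading keeps the first-listed altloc (with a
warning) and rejects insertion codes outright: the receptor recipes
address residues by number, and a structure with icodes or gaps must be
renumbered/prepared first. Selections resolve deterministically, ordered
by (chain, residue, canonical atom order: N, CA, C, O, CB, then
alphabetical), and fail loudly, listing every missing
(chain, residue, atom) key. Silent skipping is deliberately absent —
an unnoticed gap (e.g. a missing 895–908 loop) would silently corrupt
contact-number values.

## Collective variables

**ΔRMSD.** ΔRMSD = RMSD(frame → agonist-like ref) − RMSD(frame →
antagonist-like ref), each RMSD evaluated on the mobile calc selection
after superposing on the rigid fit selection. The sign convention makes
negative values agonist-like. (The alternative order of subtraction is
self-consistent but contradicts the convention that the agonist-side
minimum of the profile lies at negative ΔRMSD, so it is not used; a
`swapped()` helper flips the references when the opposite convention is
wanted.) Superposition is Kabsch via
`scipy.spatial.transform.Rotation.align_vectors` (proper rotation
guaranteed); degenerate (collinear) point sets are rejected. Tests
cross-check against an independent quaternion (Horn) implementation.

**Switching function.** f(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ) with
n = 8, m = 12 is evaluated in the geometric-sum form
Σ_{k<n} uᵏ / Σ_{k<m} uᵏ (u = r/r₀), which is algebraically identical for
u ≠ 1 and takes the removable-singularity value n/m = 2/3 at u = 1
exactly, with no 0/0 branch and no tolerance window. Contact numbers sum
f over all inter-set Cα pairs; r₀ = 0.85 nm for the NC recipes.

**α-helix RMSD (sα).** Every contiguous 6-residue window contributes
f(rᵢ) with r₀ = 0.08 nm, where rᵢ is the backbone (N, CA, C, O) RMSD of
the window to an ideal α-helical template after optimal superposition.
The template is the package's own ideal helix (φ = −57°, ψ = −47°, ideal
bond geometry, built by internal-coordinate chain extension); the
template choice shifts sα smoothly and a perfectly helical range of L
residues scores exactly L − 5.

**Crossing angle.** Helix axes are vectors between Cα centres of mass of
a start and an end residue range; the directed angle is reported in
[0°, 180°] without folding, so parallel and antiparallel packings are
distinguished.

**Side-chain criteria.** Function groups per residue type are fixed
tables (Arg NE/NH1/NH2; Lys NZ; Glu OE1/OE2; Asp OD1/OD2; Asn OD1/ND2;
Gln OE1/NE2; Ser OG; Thr OG1; His ND1/NE2; the aromatic rings of
Phe/Tyr/Trp). Distances are centroid–centroid; a close contact is
< 0.5 nm. The π-cation test requires centroid–cation distance < 0.6 nm
and the angle between the centroid→cation line and the ring-plane normal
within [60°, 120°]. That window accepts in-plane rather than stacked
geometries — unusual relative to the common convention, but applied here
exactly as its source states it; the test is symmetric under the
sign-ambiguous ring normal (SVD plane fit).

## Toy sampling engine

The integrator is overdamped (Brownian) Langevin,
x ← x − (∇V/γ)·dt + √(2 kB T dt/γ)·ξ: only equilibrium sampling of
low-dimensional CV spaces is needed for verification, so inertia and
thermostats add nothing. Discretisation bias on a harmonic well scales
as κ·dt/2γ; equipartition tests use dt small enough to keep it ≈ 1%.
The exact Boltzmann sampler inverts a trapezoidal CDF on a dense grid
(4001 nodes by default, 1-D) and provides i.i.d., correlation-free
window samples — the oracle for WHAM. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bitwise-identical
trajectories and samples.

## Umbrella sampling and WHAM

The window bias is E = k·(x − Cᵢ)², exactly as printed for the receptor
protocol (no ½ factor); k = 10 kJ/(mol·nm²) by default with 30 windows
at ≈ 0.1 nm spacing. Window seeds between two end states come from
linear Cartesian interpolation after rigid superposition — when the
superposition uses the ΔRMSD fit (core) selection the resulting ΔRMSD
ladder is monotone and evenly spaced to machine precision on the toy
pair. (Interpolation replaces normal-mode morphing as the seed
generator; the umbrella machinery needs only an ordered, roughly evenly
spaced ladder, which interpolation provides with far less apparatus.)

WHAM iterates the standard self-consistent equations on binned window
histograms until the largest window free-energy shift falls below
1e-8 kJ/mol (error on non-convergence after 1e5 iterations, reporting
the residual). Defaults: bin width = window spacing / 5; bootstrap
errors from 50 within-window resamples (warm-started from the converged
solution). Adjacent windows with disjoint histograms trigger a warning.
Empty bins are masked, never assigned infinities, and excluded from the
minimum shift and basin integrals.

## Well-tempered metadynamics

Hills are Gaussians of base height w₀ = 0.2 kJ/mol and width σ = 1.0
per CV (the receptor values; σ is in the CV's own units); the deposited
height is w₀·exp(−V(s,t)/kB·ΔT) with ΔT = (γ−1)·T and γ = 10, so the
first hill is exactly w₀, heights are bounded by w₀ and decay at
revisited points, and γ → ∞ reproduces standard metadynamics. Wall
biases are square-well: zero inside [a_low, a_up], k·((x−a+o)/s)ᵉ
outside (defaults 5/10, k = 300, e = 2, s = 1, o = 0). The FES estimate
is F(s) = −((T+ΔT)/ΔT)·V_hills(s) (walls excluded), minimum shifted to
zero. Convergence is monitored as
ΔF(t) = −kB·T·ln(Σ_A e^{−F/kBT} / Σ_B e^{−F/kBT}) between two basin
ranges along one CV axis (marginalising other axes when present),
rebuilt from the hills deposited up to each checkpoint.

The driver propagates the walker from a dense grid cache of the hill sum
(exact at the nodes, linearly interpolated forces) so the per-step cost
stays constant as hills accumulate; deposits always evaluate the exact
hill sum at the walker position. Hill pacing on the toy systems is every
75–100 integrator steps — deposition pace in physical time is only
meaningful for the all-atom system, so here it is a configurable stride.

## Trajectory statistics

- **RMSF**: frames fitted to the initial frame, then refitted to the
  resulting mean; RMSF = √⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩ per selected atom. For
  i.i.d. isotropic jitter σ the closed form is √3·σ minus a finite-size
  deflation of order √(1 − 6/3N) from the 6 rigid-body degrees of
  freedom the fit absorbs; fixtures use N ≥ 40 residues to keep that
  below 3%.
- **PMF**: −kB·T·ln(Pᵢ/Pmax) on 1-D or 2-D histograms; modal bin exactly
  0; empty bins masked. Coincides with WHAM on unbiased single-window
  data.
- **Cross-correlation**: Cij = ⟨Δrᵢ·Δrⱼ⟩/√(⟨Δrᵢ²⟩⟨Δrⱼ²⟩) of Cα
  displacement vectors about block means, computed per block, averaged
  over blocks, then over repeat trajectories. Defaults take the final
  40% of frames in 4 blocks — the fraction/count form of the common
  last-40-of-100-ns, 10-ns-block convention — with superposition on the
  window mean (fitted displacements; whether to fit is a genuine choice,
  and fitting is the default because real trajectories tumble; the
  pre-aligned synthetic generator is analysed with `fit=False`, under
  which the estimator converges exactly to the prescribed correlation).
- **Network edges**: pairs with |i−j| ≤ 10 are excluded; classes are
  anti-correlated −0.4 ≤ c < −0.2, weak 0.2 ≤ c < 0.4, moderate
  0.4 ≤ c < 0.6, strong c ≥ 0.6. The anti-correlated bin is stated in
  some sources with an overlapping upper bound (+0.2); since the classes
  must be disjoint and the bin is labelled anti-correlation, the upper
  bound is read as −0.2.
- **GROMOS clustering**: iteratively take the frame with the most
  neighbours within the fitted-RMSD cutoff (0.2 nm default) as a cluster
  with its neighbours, remove, repeat. Ties on neighbour count break to
  the lowest frame index (determinism); the representative is the member
  minimising summed distance to co-members. Output is invariant to frame
  order up to this tie-break.
- **dPCA**: φ/ψ of the interior residues of the range (termini lack a
  flanking peptide bond) are embedded as (cos θ, sin θ) before PCA
  (scikit-learn), removing angle periodicity; component variances sum to
  the total sin/cos variance, and the PMF over (PC1, PC2) uses the
  histogram PMF above.

## Synthetic ground truth and what it does not show

The generators provide known-answer inputs: an ideal helix (sα = L − 5,
Cα–Cα 0.38 nm, rise 0.15 nm emerge from the ideal internal coordinates);
a two-state pair whose mobile tail is swung symmetrically about a hinge
to a target inter-state RMSD (default 1.45 nm, so that 30 umbrella seeds
space at ≈ 0.1 nm — the receptor protocol's geometry) over a rigid core
(default 70% of a 60-residue chain), solved by bisection to 1%; Gaussian
Cα trajectories whose per-axis covariance is the prescribed Σ, making
the expected correlation matrix exactly Σij/√(Σii·Σjj); the double well
V(x) = h·((x/a)² − 1)² with h = 6.5 kJ/mol and a = 3 CV units by default
(the free-energy scale of the receptor's two-basin profile, and wide
enough that σ = 1.0 hills resolve it); and i.i.d. jittered frames.

Passing on these fixtures shows the estimators and biasing machinery are
correct — it does not show that desk-scale runs reproduce all-atom
results. Real trajectories have correlated, anisotropic fluctuations,
rugged many-dimensional landscapes, and CV time series with memory; the
toy systems deliberately have none of these. The crystal worked-example
values additionally depend on how missing loops were modelled in the
prepared structures, which is why they carry a 5% tolerance.

## Problem sizes

The verification battery uses: 30 umbrella windows × 4000 exact samples
(WHAM barrier within 0.5 kJ/mol of the analytic 6.5); a 3×10⁶-step
Langevin metadynamics run (dt = 0.01, γ_friction = 1.0, hills every 100
steps → 30 000 hills), with the barrier read from the FES averaged over
the last-third checkpoints — the well-tempered estimate oscillates
around truth, and time-averaging it is the standard variance reduction —
and the ΔF drift measured across the final third of 60 checkpoints;
10⁴ frames for correlation recovery (RMS error ≲ 0.01 against the
prescribed matrix); 2000 frames × 40 residues for RMSF; 10⁵ samples for
PMF curvature. These sizes were chosen so each quantity's statistical
error sits comfortably inside its stated tolerance.

## Known limitations

- PDB handling is single-model, icode-free, first-altloc; mmCIF and NMR
  ensembles are unsupported.
- The exact Boltzmann sampler and the metadynamics driver are 1-D
  (hills, FES reconstruction and ΔF series are dimension-general).
- WHAM assumes histogram bins small relative to the profile's curvature;
  the defaults satisfy this for the shipped protocols.
- The π-cation angular window accepts in-plane geometries by
  construction, as discussed above.
- GROMOS clustering is O(n²) in frames; intended for the ≤ 10³-frame
  analyses it is used for here.
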