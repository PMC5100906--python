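# confdyn

Collective variables, enhanced sampling and trajectory statistics for
protein conformational dynamics — built around the two-state
(agonist-like / antagonist-like) equilibrium of nuclear-receptor
ligand-binding domains (LBDs), where the position of helix 12 against the
helix 3 / helix 11 core decides the functional state.

The package is aimed at simulators who need the *analysis* side of such a
study as tested, reusable code: the geometric CVs that discriminate the
states, the biasing machinery that samples between them, and the
statistics that summarise trajectories — all verifiable at desk scale on
seeded synthetic systems with known ground truth, without any cluster
time or external downloads.

## What it computes

**Collective variables** (`confdyn.geometry`, `confdyn.worked_examples`)

- ΔRMSD progress coordinate between two reference states:
  ΔRMSD = RMSD₁ − RMSD₂, each RMSD evaluated on a mobile selection
  (the Cα of residues 903–932 in the receptor) after superposing on a
  rigid core (the 683–902 backbone). Negative values lie toward the
  agonist-like reference.
- Switching-function contact numbers
  NC = Σᵢⱼ (1 − (rᵢⱼ/r₀)⁸) / (1 − (rᵢⱼ/r₀)¹²) with r₀ = 0.85 nm,
  including the removable-singularity limit 8/12 = 2/3 at r = r₀.
  `pr_lbd_contact_numbers` packages the receptor recipes NC1 (helix 12 ×
  helix 3) and NC2 (helix 12 × helix 11).
- α-helix RMSD CV: sα = Σᵢ f(rᵢ) over contiguous 6-residue windows, rᵢ
  the backbone RMSD to an ideal α-helical template, r₀ = 0.08 nm.
- Helix crossing angles from Cα centre-of-mass vectors, side-chain
  function-group distances with the 0.5 nm close-contact rule, and the
  π-cation distance/ring-normal-angle criterion.

**Enhanced sampling** (`confdyn.sampling`, `confdyn.dynamics`)

- Umbrella sampling with the harmonic bias E = k·(ΔRMSD − Cᵢ)²
  (k = 10 kJ/(mol·nm²), 30 windows at 0.1 nm spacing by default) and
  self-consistent WHAM with bootstrap per-bin errors.
- Well-tempered metadynamics: hills of base height w₀ = 0.2 kJ/mol and
  width σ = 1.0 deposited with tempered height
  w₀·exp(−V(s,t)/kB·ΔT), ΔT = (γ−1)·T, γ = 10; square-well wall bias
  E = k·((x−a+o)/s)ᵉ (k = 300, walls at 5 and 10); FES reconstruction
  F(s) = −((T+ΔT)/ΔT)·V(s) and basin-ΔF convergence series.
- An overdamped Langevin engine and an exact (inverse-CDF) Boltzmann
  sampler on analytic potentials, so every free-energy route can be
  checked against known truth.

**Trajectory statistics** (`confdyn.analysis`)

RMSD series and RMSF, histogram PMFs (−kB·T·ln Pᵢ/Pmax), block-averaged
Pearson cross-correlation of Cα displacement vectors with the
|i−j| ≤ 10 exclusion and the four-class network edge list, GROMOS
neighbour-count clustering at a 0.2 nm fitted-RMSD cutoff with medoid
representatives, and dihedral PCA on sin/cos-embedded φ/ψ angles.

**Synthetic ground truth** (`confdyn.synthetic`)

Seeded generators for ideal α-helices, two-state conformer pairs with a
rigid core and mobile tail, correlated-Gaussian Cα trajectories with a
prescribed covariance, the analytic double well V(x) = h·((x/a)²−1)²,
and jittered trajectories.

## Worked example

```python
import numpy as np
import confdyn as cd

# two-state toy pair (rigid core, mobile tail) and its dRMSD coordinate
spec = cd.TwoStateToySpec()
agonist_like, antagonist_like = cd.build_two_state_pair(spec)
coord = cd.DeltaRmsdSpec(
    agonist_like, antagonist_like,
    fit_selection=cd.AtomSelection.backbone(1, spec.n_core),
    calc_selection=cd.AtomSelection.ca(spec.n_core + 1, spec.chain_length),
)
print("dRMSD(agonist-like) =", round(cd.delta_rmsd(agonist_like, coord), 3), "nm")
print("dRMSD(antagonist-like) =", round(cd.delta_rmsd(antagonist_like, coord), 3), "nm")

# umbrella sampling + WHAM on a double well with a known 6.5 kJ/mol barrier
well = cd.double_well_potential(barrier_height=6.5, well_separation=3.0)
windows = []
for i, c in enumerate(np.linspace(-4.5, 4.5, 30)):
    w = cd.UmbrellaWindow(center=c, force_constant=10.0)
    w.samples = cd.boltzmann_sampler(well, w, temperature=300.0, n=4000, seed=i)
    windows.append(w)
profile = cd.wham(windows, temperature=300.0,
                  bin_edges=np.arange(-5, 5.0001, 0.0625))
print("WHAM barrier =", round(profile.barrier_between((-4, -2), (2, 4)), 2), "kJ/mol")

sw = cd.SwitchingParams(r0=0.85)
print("f(r0) =", round(cd.switching_function(0.85, sw), 4))
```

prints

```
dRMSD(agonist-like) = -1.451 nm
dRMSD(antagonist-like) = 1.451 nm
WHAM barrier = 6.72 kJ/mol
f(r0) = 0.6667
```

The two references score ±d on the ΔRMSD coordinate (d their mutual
fitted distance on the mobile tail), WHAM recovers the analytic barrier
to within a few tenths of kJ/mol from exactly sampled windows, and the
switching function takes its analytic limit 2/3 at the contact cutoff.

A command-line interface mirrors the library
(`confdyn make-fixture | umbrella-run | wham | metad-run | fes |
converge | rmsf | pmf | correlate | network | cluster | dpca`).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
details and known limitations.
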