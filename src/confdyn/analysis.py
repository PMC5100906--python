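"""Trajectory statistics: RMSD/RMSF series, PMFs, correlation networks,
GROMOS clustering and dihedral PCA.

Conventions follow common practice for nuclear-receptor LBD trajectory
analysis: Cα-based measures, block-averaged Pearson cross-correlation of
residue displacement vectors with the |i − j| ≤ 10 sequence-neighbour
exclusion, PMFs as −kB·T·ln(Pᵢ/Pmax) so the modal bin sits at zero, and
iterative neighbour-count (GROMOS) clustering under a pairwise fitted
RMSD cutoff with the in-cluster distance-minimising member as the
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .constants import KB
from .geometry import apply_transform, kabsch_superpose, rmsd_after_fit
from .sampling import FreeEnergyProfile
from .structure_io import AtomSelection, Structure, Trajectory

__all__ = [
    "PmfSpec",
    "CorrelationMatrix",
    "NetworkEdge",
    "ClusterSet",
    "rmsd_series",
    "rmsf",
    "pmf_from_samples",
    "cross_correlation",
    "correlation_network",
    "gromos_cluster",
    "dpca",
]


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    fit_sel: AtomSelection,
    calc_sel: AtomSelection,
) -> np.ndarray:
    """Per-frame RMSD (nm) on ``calc_sel`` after fitting each frame on ``fit_sel``."""
    return np.array(
        [
            rmsd_after_fit(trajectory.frame(i), reference, fit_sel, calc_sel)
            for i in range(trajectory.n_frames)
        ]
    )


def _fit_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(coords)
    for i in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[i], reference)
        fitted[i] = apply_transform(coords[i], rot, trans)
    return fitted


def rmsf(trajectory: Trajectory, fit_sel: AtomSelection) -> np.ndarray:
    """Per-atom RMSF (nm) over the selection, after fitting to the mean.

    Frames are first fitted to the initial frame, the mean structure is
    formed, frames are refitted to that mean, and the RMSF of each selected
    atom about its mean position is √⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩.  For i.i.d.
    isotropic jitter of width σ per coordinate the expected RMSF is √3·σ.
    """
    idx = fit_sel.resolve(trajectory.topology)
    coords = trajectory.coords[:, idx, :]
    fitted = _fit_frames(coords, coords[0])
    fitted = _fit_frames(coords, fitted.mean(axis=0))
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# PMF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PmfSpec:
    """Binning and temperature for a histogram PMF (1-D or 2-D)."""

    temperature: float = 300.0
    bin_edges: np.ndarray | tuple[np.ndarray, np.ndarray] = None

    def __post_init__(self) -> None:
        if self.bin_edges is None:
            raise ValueError("bin edges are required")
        edges = self.bin_edges
        if not isinstance(edges, tuple):
            edges = (edges,)
        for e in edges:
            e = np.asarray(e)
            if e.size < 3 or np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing, >= 2 bins")


def pmf_from_samples(samples: np.ndarray, spec: PmfSpec) -> FreeEnergyProfile:
    """PMF = −kB·T·ln(Pᵢ/Pmax) from sampled CV values.

    The modal bin is exactly zero by construction; empty bins are masked,
    not set to infinity.
    """
    samples = np.asarray(samples, dtype=float)
    if isinstance(spec.bin_edges, tuple):
        ex, ey = (np.asarray(e, dtype=float) for e in spec.bin_edges)
        hist, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=(ex, ey))
        centers = (0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]))
    else:
        edges = np.asarray(spec.bin_edges, dtype=float)
        hist, _ = np.histogram(samples, bins=edges)
        hist = hist.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])
    empty = hist == 0
    pmax = hist.max()
    with np.errstate(divide="ignore"):
        values = np.where(~empty, -KB * spec.temperature * np.log(hist / pmax), np.nan)
    return FreeEnergyProfile(centers=centers, values=values, mask=empty)


# ---------------------------------------------------------------------------
# Cross-correlation networks
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Residue × residue Pearson coefficients with the averaging scheme recorded."""

    residue_numbers: np.ndarray
    matrix: np.ndarray
    block_length: int
    n_blocks_averaged: int
    n_repeats_averaged: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(m) > 1.0 + 1e-10):
            raise ValueError("correlation coefficients must lie in [-1, 1]")
        self.matrix = np.clip(m, -1.0, 1.0)


def _block_correlation(disp: np.ndarray) -> np.ndarray:
    """Pearson Cij of (n_frames, n_res, 3) displacement vectors about their mean."""
    d = disp - disp.mean(axis=0, keepdims=True)
    inner = np.einsum("fik,fjk->ij", d, d) / d.shape[0]
    norm = np.sqrt(np.outer(np.diag(inner), np.diag(inner)))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(norm > 0, inner / norm, 0.0)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def cross_correlation(
    trajectories: Trajectory | Sequence[Trajectory],
    ca_sel: AtomSelection,
    n_blocks: int = 4,
    analysis_fraction: float = 0.4,
    fit: bool = True,
) -> CorrelationMatrix:
    """Block-averaged Pearson cross-correlation of Cα displacement vectors.

    For each trajectory the final ``analysis_fraction`` of frames is split
    into ``n_blocks`` equal blocks; per block, Cij is the normalised inner
    product ⟨Δrᵢ·Δrⱼ⟩/√(⟨Δrᵢ²⟩⟨Δrⱼ²⟩) of displacements about the block
    mean.  Block matrices are averaged within a trajectory, then across
    repeat trajectories.  The defaults (last 40%, 4 blocks) mirror the
    10-ns-blocks-of-the-last-40-ns convention, expressed as fractions so
    toy trajectories scale.  With ``fit`` the frames are superposed on the
    analysis-window mean before measuring displacements; pre-aligned
    synthetic trajectories may switch it off.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    per_traj: list[np.ndarray] = []
    residue_numbers = None
    block_len = 0
    for traj in trajectories:
        idx = ca_sel.resolve(traj.topology)
        if residue_numbers is None:
            residue_numbers = np.array(
                [traj.topology.atoms[i].residue_number for i in idx]
            )
        coords = traj.coords[:, idx, :]
        start = int(round(coords.shape[0] * (1.0 - analysis_fraction)))
        window = coords[start:]
        if window.shape[0] < n_blocks:
            raise ValueError(
                f"analysis window of {window.shape[0]} frames cannot hold "
                f"{n_blocks} blocks"
            )
        if fit:
            window = _fit_frames(window, window.mean(axis=0))
        block_len = window.shape[0] // n_blocks
        blocks = [
            _block_correlation(window[b * block_len:(b + 1) * block_len])
            for b in range(n_blocks)
        ]
        per_traj.append(np.mean(blocks, axis=0))
    matrix = np.mean(per_traj, axis=0)
    matrix = 0.5 * (matrix + matrix.T)
    return CorrelationMatrix(
        residue_numbers=residue_numbers,
        matrix=matrix,
        block_length=block_len,
        n_blocks_averaged=n_blocks,
        n_repeats_averaged=len(per_traj),
    )


#: (label, lower, upper) correlation classes; the anti-correlated bin is
#: −0.4 ≤ ccc < −0.2 (the published caption's overlapping bound read as a
#: sign typo — see the methods note).
DEFAULT_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("anti-correlated", -0.4, -0.2),
    ("weak", 0.2, 0.4),
    ("moderate", 0.4, 0.6),
    ("strong", 0.6, 1.0 + 1e-12),
)


@dataclass(frozen=True)
class NetworkEdge:
    """A correlation-network edge between two sequence-distant residues."""

    residue_i: int
    residue_j: int
    coefficient: float
    label: str

    def __post_init__(self) -> None:
        if abs(self.residue_i - self.residue_j) <= 10:
            raise ValueError("network edges require |i - j| > 10")


def correlation_network(
    matrix: CorrelationMatrix,
    classes: tuple[tuple[str, float, float], ...] = DEFAULT_CLASSES,
    min_sequence_separation: int = 10,
) -> list[NetworkEdge]:
    """Classified edge list from a correlation matrix.

    Residue pairs with |i − j| ≤ 10 are excluded (sequence-neighbour
    correlation removal); remaining coefficients are binned into the class
    thresholds, and values falling in no class produce no edge.
    """
    edges: list[NetworkEdge] = []
    res = matrix.residue_numbers
    n = len(res)
    for a in range(n):
        for b in range(a + 1, n):
            if abs(int(res[a]) - int(res[b])) <= min_sequence_separation:
                continue
            c = float(matrix.matrix[a, b])
            for label, lo, hi in classes:
                if lo <= c < hi:
                    edges.append(NetworkEdge(int(res[a]), int(res[b]), c, label))
                    break
    return edges


def network_to_graph(edges: Sequence[NetworkEdge]):
    """Edge list as a networkx graph (edge attributes: coefficient, label)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(e.residue_i, e.residue_j, coefficient=e.coefficient, label=e.label)
    return g


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Frame partition with one representative (medoid) per cluster."""

    clusters: list[list[int]]
    representatives: list[int]
    cutoff: float

    def __post_init__(self) -> None:
        flat = [i for c in self.clusters for i in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must partition the frames")
        for members, rep in zip(self.clusters, self.representatives):
            if rep not in members:
                raise ValueError("representative must belong to its cluster")


def pairwise_rmsd_matrix(trajectory: Trajectory, sel: AtomSelection) -> np.ndarray:
    """Symmetric matrix of pairwise fitted RMSDs (nm) on the selection."""
    idx = sel.resolve(trajectory.topology)
    coords = trajectory.coords[:, idx, :]
    n = coords.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(coords[i], coords[j])
            dist[i, j] = dist[j, i] = r
    return dist


def gromos_cluster(
    trajectory: Trajectory,
    ca_sel: AtomSelection,
    cutoff: float = 0.2,
) -> ClusterSet:
    """Iterative neighbour-count clustering under a fitted-RMSD cutoff.

    Repeatedly the frame with the most neighbours within ``cutoff`` is
    taken as a cluster centre, it and its neighbours form a cluster and
    are removed, until no frames remain.  Ties on neighbour count break to
    the lowest frame index.  Each cluster's representative is the member
    whose summed distance to its co-members is minimal.
    """
    if trajectory.n_frames < 1:
        raise ValueError("need at least one frame")
    dist = pairwise_rmsd_matrix(trajectory, ca_sel)
    n = dist.shape[0]
    within = dist <= cutoff
    np.fill_diagonal(within, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    reps: list[int] = []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[center] & remaining)[0]
        sums = dist[np.ix_(members, members)].sum(axis=1)
        rep = int(members[np.argmin(sums)])
        clusters.append([int(m) for m in members])
        reps.append(rep)
        remaining[members] = False
    return ClusterSet(clusters=clusters, representatives=reps, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Dihedral PCA
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def backbone_dihedrals(
    trajectory: Trajectory, residue_range: tuple[int, int],
    chain_id: str | None = None,
) -> np.ndarray:
    """φ/ψ angles (radians) per frame for the interior residues of a range.

    Chain termini inside the range are skipped (φ needs the preceding C,
    ψ the following N).  Returns (n_frames, 2·n_interior).
    """
    topo = trajectory.topology
    chain = chain_id if chain_id is not None else topo.chain_ids()[0]
    first, last = residue_range
    atom_idx: list[tuple[int, int, int, int]] = []
    for res in range(max(first, min(topo.residue_numbers(chain)) + 1),
                     min(last, max(topo.residue_numbers(chain)) - 1) + 1):
        phi = tuple(
            topo.atom_index(chain, r, name)
            for r, name in ((res - 1, "C"), (res, "N"), (res, "CA"), (res, "C"))
        )
        psi = tuple(
            topo.atom_index(chain, r, name)
            for r, name in ((res, "N"), (res, "CA"), (res, "C"), (res + 1, "N"))
        )
        atom_idx.extend([phi, psi])
    angles = np.empty((trajectory.n_frames, len(atom_idx)))
    for f in range(trajectory.n_frames):
        c = trajectory.coords[f]
        for k, (i, j, l, m) in enumerate(atom_idx):
            angles[f, k] = _dihedral(c[i], c[j], c[l], c[m])
    return angles


@dataclass
class DpcaResult:
    """Projections, explained variance and a 2-D PMF on the first two PCs."""

    projections: np.ndarray
    explained_variance: np.ndarray
    pmf: FreeEnergyProfile


def dpca(
    trajectory: Trajectory,
    residue_range: tuple[int, int],
    temperature: float = 300.0,
    n_components: int | None = None,
    n_bins: int = 32,
    chain_id: str | None = None,
) -> DpcaResult:
    """Dihedral PCA: φ/ψ → (cos θ, sin θ) coordinates → covariance PCA.

    The circular dihedrals are embedded on the unit circle before PCA so
    the principal components are free of angle-periodicity artefacts; the
    PMF over (PC1, PC2) is the histogram PMF at ``temperature``.
    """
    angles = backbone_dihedrals(trajectory, residue_range, chain_id=chain_id)
    features = np.concatenate([np.cos(angles), np.sin(angles)], axis=1)
    n_comp = n_components or min(features.shape)
    pca = PCA(n_components=n_comp)
    proj = pca.fit_transform(features)
    var = pca.explained_variance_
    if proj.shape[1] >= 2 and np.ptp(proj[:, 0]) > 0 and np.ptp(proj[:, 1]) > 0:
        ex = np.linspace(proj[:, 0].min(), proj[:, 0].max() + 1e-9, n_bins + 1)
        ey = np.linspace(proj[:, 1].min(), proj[:, 1].max() + 1e-9, n_bins + 1)
        pmf = pmf_from_samples(proj[:, :2], PmfSpec(temperature, (ex, ey)))
    else:
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        pmf = FreeEnergyProfile(
            centers=0.5 * (edges[:-1] + edges[1:]),
            values=np.full(n_bins, np.nan),
            mask=np.ones(n_bins, dtype=bool),
        )
    return DpcaResult(projections=proj, explained_variance=var, pmf=pmf)
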