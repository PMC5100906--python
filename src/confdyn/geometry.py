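"""Geometric collective variables on structures and frames.

Implements the full CV set used to characterise the two functional states
of a nuclear-receptor ligand-binding domain: fitted RMSDs and the signed
ΔRMSD progress coordinate between an agonist-like and an antagonist-like
reference, rational switching-function contact numbers (NC), the α-helix
RMSD secondary-structure CV (sα), inter-helix crossing angles from
centre-of-mass vectors, side-chain function-group distances with the
0.5 nm close-contact rule, and the printed π-cation criterion.

Sign convention for ΔRMSD: RMSD-to-agonistic − RMSD-to-antagonistic, so a
more negative value means a conformation closer to the agonist-like
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import AtomSelection, Structure, select_coords
from .synthetic import build_ideal_helix

__all__ = [
    "SwitchingParams",
    "HelixAxisSpec",
    "DeltaRmsdSpec",
    "FUNCTION_GROUPS",
    "AROMATIC_RINGS",
    "CATION_CENTERS",
    "kabsch_superpose",
    "rmsd_after_fit",
    "delta_rmsd",
    "helix_cross_angle",
    "switching_function",
    "contact_number",
    "alpha_helix_rmsd_cv",
    "sidechain_group_distance",
    "is_close_contact",
    "is_pi_cation",
]


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` minimises the least-squares
    deviation; the rotation is proper (det = +1).

    Degenerate inputs (fewer than 3 points, mismatched sizes, or all
    points collinear) raise ``ValueError``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_com = mobile.mean(axis=0)
    ref_com = reference.mean(axis=0)
    mob_c = mobile - mob_com
    ref_c = reference - ref_com
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2 or \
       np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) configuration")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref_com - rotation @ mob_com
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an (n, 3) coordinate matrix."""
    return coords @ rotation.T + translation


def rmsd_after_fit(
    frame: Structure,
    reference: Structure,
    fit_sel: AtomSelection,
    calc_sel: AtomSelection,
) -> float:
    """RMSD on ``calc_sel`` after superposing the frame on ``fit_sel``.

    The rigid transform is fitted on the fit selection only and then
    applied to the calculation selection, so the calculation atoms are
    measured in the fitted frame — the construction that maximises the
    contrast of a mobile segment against a rigid core.
    """
    rot, trans, _ = kabsch_superpose(
        select_coords(frame, fit_sel), select_coords(reference, fit_sel)
    )
    moved = apply_transform(select_coords(frame, calc_sel), rot, trans)
    ref = select_coords(reference, calc_sel)
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


@dataclass(frozen=True)
class DeltaRmsdSpec:
    """The two reference states and selections defining the ΔRMSD coordinate.

    The fit selection plays the rigid-core role (the 683–902 backbone in
    the receptor), the calc selection the mobile segment (Cα of 903–932).
    With ``agonistic_negative`` (the default) a frame identical to the
    agonist-like reference scores −d, where d is the inter-reference
    distance on the calc set.
    """

    ref_agonistic: Structure
    ref_antagonistic: Structure
    fit_selection: AtomSelection
    calc_selection: AtomSelection
    agonistic_negative: bool = True

    def swapped(self) -> "DeltaRmsdSpec":
        return DeltaRmsdSpec(
            ref_agonistic=self.ref_antagonistic,
            ref_antagonistic=self.ref_agonistic,
            fit_selection=self.fit_selection,
            calc_selection=self.calc_selection,
            agonistic_negative=self.agonistic_negative,
        )


def delta_rmsd(frame: Structure, spec: DeltaRmsdSpec) -> float:
    """Signed ΔRMSD = RMSD-to-agonistic − RMSD-to-antagonistic (nm)."""
    r_ago = rmsd_after_fit(frame, spec.ref_agonistic, spec.fit_selection,
                           spec.calc_selection)
    r_ant = rmsd_after_fit(frame, spec.ref_antagonistic, spec.fit_selection,
                           spec.calc_selection)
    value = r_ago - r_ant
    return value if spec.agonistic_negative else -value


# ---------------------------------------------------------------------------
# Helix crossing angle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAxisSpec:
    """A helix-axis vector from Cα centres of mass of two residue ranges.

    The vector points from the COM of the Cα atoms of ``start_residues``
    (inclusive range) to that of ``end_residues``.
    """

    start_residues: tuple[int, int]
    end_residues: tuple[int, int]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        s, e = self.start_residues, self.end_residues
        if s[1] < s[0] or e[1] < e[0]:
            raise ValueError("residue ranges must be non-empty")
        if not (s[1] < e[0] or e[1] < s[0]):
            raise ValueError("start and end residue ranges must not overlap")

    def vector(self, frame: Structure) -> np.ndarray:
        start = select_coords(
            frame, AtomSelection.ca(*self.start_residues, chain_id=self.chain_id)
        ).mean(axis=0)
        end = select_coords(
            frame, AtomSelection.ca(*self.end_residues, chain_id=self.chain_id)
        ).mean(axis=0)
        return end - start


def helix_cross_angle(frame: Structure, axis_a: HelixAxisSpec,
                      axis_b: HelixAxisSpec) -> float:
    """Angle (degrees, [0, 180]) between two directed helix-axis vectors.

    The directed angle is reported without folding to [0, 90], so parallel
    and antiparallel packings are distinguished.
    """
    va = axis_a.vector(frame)
    vb = axis_b.vector(frame)
    cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Rational switching function and contact numbers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function f(r) = (1 − (r/r0)ⁿ)/(1 − (r/r0)ᵐ)."""

    r0: float
    n: int = 8
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("exponents must satisfy 0 < n < m")


def switching_function(r: np.ndarray | float, params: SwitchingParams) -> np.ndarray | float:
    """Evaluate the rational switch, continuous through the r = r0 point.

    Computed as the geometric-sum form Σ_{k<n} uᵏ / Σ_{k<m} uᵏ with
    u = r/r0, which is algebraically identical to the rational form for
    u ≠ 1 and takes the removable-singularity limit n/m at u = 1 exactly.
    """
    u = np.asarray(r, dtype=float) / params.r0
    powers = u[..., None] ** np.arange(params.m)
    num = powers[..., : params.n].sum(axis=-1)
    den = powers.sum(axis=-1)
    out = num / den
    return float(out) if np.isscalar(r) else out


def contact_number(coords_a: np.ndarray, coords_b: np.ndarray,
                   params: SwitchingParams) -> float:
    """Switching-function contact count between two Cα coordinate sets.

    NC = Σᵢ Σⱼ f(rᵢⱼ) over all inter-set pairs; strictly decreasing in
    every pairwise distance and bounded by N₁·N₂.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.size == 0 or coords_b.size == 0:
        raise ValueError("coordinate sets must be nonempty")
    r = cdist(coords_a, coords_b)
    return float(np.sum(switching_function(r, params)))


# ---------------------------------------------------------------------------
# α-helix RMSD CV (sα)
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[int, np.ndarray] = {}


def _helix_template(window: int = 6) -> np.ndarray:
    """Backbone (N, CA, C, O) coordinates of an ideal α-helical window."""
    if window not in _TEMPLATE_CACHE:
        helix = build_ideal_helix(window)
        _TEMPLATE_CACHE[window] = helix.coords
    return _TEMPLATE_CACHE[window]


def alpha_helix_rmsd_cv(
    frame: Structure,
    residue_range: tuple[int, int],
    params: SwitchingParams = SwitchingParams(r0=0.08),
    chain_id: str | None = None,
) -> float:
    """Secondary-structure CV sα: helical content of a residue range.

    Every contiguous 6-residue window contributes f(rᵢ), where rᵢ is the
    backbone (N, CA, C, O) RMSD of the window to an ideal α-helical
    template after optimal superposition and f is the rational switch with
    r0 = 0.08 nm.  A perfectly helical range of L residues scores L − 5;
    an extended chain scores ≈ 0.
    """
    first, last = residue_range
    n_res = last - first + 1
    if n_res < 6:
        raise ValueError("residue range must span at least 6 residues")
    template = _helix_template(6)
    total = 0.0
    for start in range(first, last - 4):
        sel = AtomSelection.backbone(start, start + 5, chain_id=chain_id)
        window_coords = select_coords(frame, sel)
        _, _, r = kabsch_superpose(window_coords, template)
        total += switching_function(r, params)
    return float(total)


# ---------------------------------------------------------------------------
# Side-chain function groups, contacts, π-cation
# ---------------------------------------------------------------------------

#: Side-chain function-group atoms per residue type (polar/charged groups).
FUNCTION_GROUPS: Mapping[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "HIS": ("ND1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: Aromatic ring atoms (subset of FUNCTION_GROUPS used for π systems).
AROMATIC_RINGS: Mapping[str, tuple[str, ...]] = {
    "PHE": FUNCTION_GROUPS["PHE"],
    "TYR": FUNCTION_GROUPS["TYR"],
    "TRP": FUNCTION_GROUPS["TRP"],
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Positively charged centres.
CATION_CENTERS: Mapping[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}


def _group_centroid(
    frame: Structure,
    chain_id: str,
    residue_number: int,
    table: Mapping[str, tuple[str, ...]],
) -> np.ndarray:
    res_name = None
    for atom in frame.atoms:
        if atom.chain_id == chain_id and atom.residue_number == residue_number:
            res_name = atom.residue_name
            break
    if res_name is None:
        raise KeyError(f"residue ({chain_id!r}, {residue_number}) not in structure")
    if res_name not in table:
        raise KeyError(f"no function-group entry for residue type {res_name!r}")
    coords = np.array(
        [frame.lookup(chain_id, residue_number, name).coordinates
         for name in table[res_name]]
    )
    return coords.mean(axis=0), coords


def sidechain_group_distance(
    frame: Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    table: Mapping[str, tuple[str, ...]] = FUNCTION_GROUPS,
) -> float:
    """Distance (nm) between the function-group centroids of two residues.

    E.g. for an Arg–Glu pair: centre of the three guanidinium nitrogens to
    the centre of the two carboxylate oxygens.
    """
    cen_a, _ = _group_centroid(frame, *res_a, table)
    cen_b, _ = _group_centroid(frame, *res_b, table)
    return float(np.linalg.norm(cen_a - cen_b))


def is_close_contact(distance: float) -> bool:
    """True iff a side-chain function-group distance is below 0.5 nm (5 Å)."""
    return bool(distance < 0.5)


def _ring_normal(ring_coords: np.ndarray) -> np.ndarray:
    centered = ring_coords - ring_coords.mean(axis=0)
    # least-variance direction = plane normal
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def is_pi_cation(
    frame: Structure,
    aromatic_res: tuple[str, int],
    cationic_res: tuple[str, int],
    distance_cutoff: float = 0.6,
    angle_window: tuple[float, float] = (60.0, 120.0),
) -> bool:
    """π-cation criterion: ring-centroid distance < 0.6 nm and the angle
    between the centroid→cation line and the ring-plane normal inside
    [60°, 120°].

    The angle window is applied exactly as stated by its source, which
    places the accepted cation near the ring plane rather than stacked
    above it; see the methods note for discussion.  The test is symmetric
    under flipping the (sign-ambiguous) ring normal.
    """
    ring_cen, ring_coords = _group_centroid(frame, *aromatic_res, AROMATIC_RINGS)
    cat_cen, _ = _group_centroid(frame, *cationic_res, CATION_CENTERS)
    sep = cat_cen - ring_cen
    dist = float(np.linalg.norm(sep))
    if dist >= distance_cutoff:
        return False
    normal = _ring_normal(ring_coords)
    cosang = np.clip(sep @ normal / dist, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return angle_window[0] <= angle <= angle_window[1]
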