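"""Receptor-specific CV definitions for the progesterone-receptor LBD.

The collective variables that characterise the agonist/antagonist
equilibrium of the PR ligand-binding domain are fixed residue-range
recipes on the crystal models (author numbering, residues 683–933):

* NC1 — switching-function Cα contact number between helix 12
  (residues 908–922) and helix 3 (residues 713–734), r0 = 0.85 nm;
* NC2 — same between helix 12 and helix 11 (residues 882–898);
* the helix 11 / helix 3 crossing angle from Cα centre-of-mass vectors
  (883–886 → 894–897 and 712–715 → 730–733);
* the ΔRMSD progress coordinate fitted on the 683–902 backbone and
  evaluated on the 903–932 Cα set.

These helpers evaluate the recipes on any prepared (gap-free) structure
of the domain.  The crystal references themselves (PDB 1A28 chain A and
2OVH with its 895–908 loop modelled) are inputs the user supplies.
"""

from __future__ import annotations

from .geometry import (
    DeltaRmsdSpec,
    HelixAxisSpec,
    SwitchingParams,
    contact_number,
    helix_cross_angle,
)
from .structure_io import AtomSelection, Structure, select_coords

__all__ = [
    "HELIX12_RANGE",
    "HELIX3_RANGE",
    "HELIX11_RANGE",
    "NC_SWITCHING",
    "HELIX11_AXIS",
    "HELIX3_AXIS",
    "pr_lbd_contact_numbers",
    "pr_lbd_cross_angle",
    "pr_lbd_delta_rmsd_spec",
]

HELIX12_RANGE = (908, 922)
HELIX3_RANGE = (713, 734)
HELIX11_RANGE = (882, 898)

#: Rational switch for the Cα contact numbers, r0 = 0.85 nm, n/m = 8/12.
NC_SWITCHING = SwitchingParams(r0=0.85, n=8, m=12)

#: Helix-axis vectors for the crossing angle (Cα COM tail → head).
HELIX11_AXIS = HelixAxisSpec(start_residues=(883, 886), end_residues=(894, 897))
HELIX3_AXIS = HelixAxisSpec(start_residues=(712, 715), end_residues=(730, 733))


def pr_lbd_contact_numbers(structure: Structure,
                           chain_id: str | None = None) -> tuple[float, float]:
    """(NC1, NC2) of a prepared PR LBD structure.

    On the crystal antagonist model the pair is near (1.0, 34); on the
    agonist model near (16.7, 31.2) — helix 12 swaps its packing partner
    between the two functional states.
    """
    h12 = select_coords(structure, AtomSelection.ca(*HELIX12_RANGE, chain_id=chain_id))
    h3 = select_coords(structure, AtomSelection.ca(*HELIX3_RANGE, chain_id=chain_id))
    h11 = select_coords(structure, AtomSelection.ca(*HELIX11_RANGE, chain_id=chain_id))
    nc1 = contact_number(h12, h3, NC_SWITCHING)
    nc2 = contact_number(h12, h11, NC_SWITCHING)
    return nc1, nc2


def pr_lbd_cross_angle(structure: Structure, chain_id: str | None = None) -> float:
    """Helix 11 / helix 3 crossing angle (degrees) of a prepared structure."""
    h11 = HelixAxisSpec(HELIX11_AXIS.start_residues, HELIX11_AXIS.end_residues,
                        chain_id=chain_id)
    h3 = HelixAxisSpec(HELIX3_AXIS.start_residues, HELIX3_AXIS.end_residues,
                       chain_id=chain_id)
    return helix_cross_angle(structure, h11, h3)


def pr_lbd_delta_rmsd_spec(ref_agonistic: Structure,
                           ref_antagonistic: Structure) -> DeltaRmsdSpec:
    """The ΔRMSD coordinate between the two crystal end states.

    Fit on the 683–902 backbone, evaluate on the 903–932 Cα set; negative
    values lie toward the agonist-like reference.
    """
    return DeltaRmsdSpec(
        ref_agonistic=ref_agonistic,
        ref_antagonistic=ref_antagonistic,
        fit_selection=AtomSelection.backbone(683, 902),
        calc_selection=AtomSelection.ca(903, 932),
    )
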