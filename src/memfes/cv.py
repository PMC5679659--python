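"""Collective variables describing protein position and orientation
relative to a membrane, and the binding-mode classification built on them.

Four coordinates are used throughout:

``|z|``     distance between the protein Calpha COM and the upper-leaflet
            P-atom COM, projected on the membrane normal (Angstrom, >= 0);
``theta``   angle between the protein long axis and the membrane normal (deg);
``phi``     angle between the protein short axis and the membrane normal (deg);
``min z_r`` minimum over residues r of the Calpha z-coordinate relative to
            the upper-leaflet P plane (Angstrom, signed) — the insertion
            depth coordinate.

Angles are reported on [0, 180] deg as the angle between the *oriented*
axis (pink-group -> blue-group direction) and the +normal; an unsigned-line
convention would fold the two binding orientations onto each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .structures import LEAFLET_LOWER, LEAFLET_UPPER, ToyStructure
from .synthetic import LONG_AXIS_GROUPS, SHORT_AXIS_GROUPS, _ranges_to_set

NM_TO_A = 10.0

#: Pocket-opening residue used to label unbiased binding outcomes.
G61 = 61


@dataclass(frozen=True)
class MembraneFrameRef:
    """Membrane reference frame: unit normal plus leaflet P-plane heights."""

    normal: np.ndarray
    upper_p_z: float  # nm
    lower_p_z: float  # nm

    def __post_init__(self):
        if self.upper_p_z <= self.lower_p_z:
            raise ValueError("upper leaflet must lie above the lower leaflet")


@dataclass
class CVSample:
    """One frame's worth of collective variables."""

    time: float
    z_abs: float    # Angstrom
    theta: float    # deg, [0, 180]
    phi: float      # deg, [0, 180]
    min_zr: float   # Angstrom, signed
    replica: int = -1

    def __post_init__(self):
        if self.z_abs < 0:
            raise ValueError("z_abs must be >= 0")
        for name in ("theta", "phi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name}={v} outside [0, 180] deg")


class BindingMode(str, Enum):
    PRONE = "Prone"
    SUPINE = "Supine"
    UNBOUND = "Unbound"
    INTERMEDIATE = "Intermediate"


@dataclass(frozen=True)
class ModeThresholds:
    """Classification cutoffs (config-exposed; the angle cutoffs follow the
    observed orientation basins, the z cutoffs are package conventions)."""

    prone_phi_min: float = 140.0
    supine_phi_max: float = 40.0
    assoc_zr_max: float = 10.0   # membrane-associated iff min z_r below this
    bulk_zr_min: float = 20.0    # unbound iff min z_r above this


def membrane_normal(frame: ToyStructure) -> MembraneFrameRef:
    """Membrane frame from leaflet-tagged P atoms: the unit vector from the
    lower-leaflet P COM to the upper-leaflet P COM, plus both plane heights."""
    up = frame.leaflet == LEAFLET_UPPER
    lo = frame.leaflet == LEAFLET_LOWER
    if not up.any() or not lo.any():
        raise ValueError("both leaflets need at least one tagged P atom")
    com_up = frame.xyz[up].mean(axis=0)
    com_lo = frame.xyz[lo].mean(axis=0)
    v = com_up - com_lo
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("leaflet P COMs coincide")
    return MembraneFrameRef(normal=v / n, upper_p_z=float(com_up[2]),
                            lower_p_z=float(com_lo[2]))


def _group_com(ca_xyz: np.ndarray, ca_resids: np.ndarray, ranges) -> np.ndarray:
    sel = np.isin(ca_resids, sorted(_ranges_to_set(ranges)))
    if not sel.any():
        raise ValueError("axis group has no Calpha atoms")
    return ca_xyz[sel].mean(axis=0)


def protein_axes(frame: ToyStructure):
    """(long, short) unit axis vectors from the residue-group Calpha COMs,
    oriented pink-group -> blue-group."""
    ca = frame.ca_mask()
    xyz, resids = frame.xyz[ca], frame.resids[ca]
    axes = []
    for groups in (LONG_AXIS_GROUPS, SHORT_AXIS_GROUPS):
        v = (_group_com(xyz, resids, groups["blue"])
             - _group_com(xyz, resids, groups["pink"]))
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValueError("axis group COMs coincide")
        axes.append(v / n)
    return axes[0], axes[1]


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def compute_cvs(frame: ToyStructure, ref: MembraneFrameRef,
                time: float = 0.0, replica: int = -1) -> CVSample:
    """All four CVs for one frame (protein + membrane in one structure)."""
    long_ax, short_ax = protein_axes(frame)
    ca = frame.ca_mask()
    ca_z = frame.xyz[ca, 2]
    return CVSample(
        time=time,
        z_abs=abs(float(ca_z.mean()) - ref.upper_p_z) * NM_TO_A,
        theta=_angle_deg(long_ax, ref.normal),
        phi=_angle_deg(short_ax, ref.normal),
        min_zr=(float(ca_z.min()) - ref.upper_p_z) * NM_TO_A,
        replica=replica,
    )


def classify_mode(cv: CVSample,
                  thresholds: ModeThresholds = ModeThresholds()) -> BindingMode:
    """Total classification: Prone / Supine when membrane-associated with the
    short axis in the respective orientation band, Unbound in bulk, otherwise
    Intermediate."""
    t = thresholds
    associated = cv.min_zr < t.assoc_zr_max
    if associated and cv.phi > t.prone_phi_min:
        return BindingMode.PRONE
    if associated and cv.phi < t.supine_phi_max:
        return BindingMode.SUPINE
    if cv.min_zr > t.bulk_zr_min:
        return BindingMode.UNBOUND
    return BindingMode.INTERMEDIATE


def g61_insertion_depth(frame: ToyStructure, ref: MembraneFrameRef,
                        resid: int = G61) -> float:
    """Signed z of the pocket-opening residue's Calpha relative to the
    upper-leaflet P plane, in Angstrom. Negative means inserted."""
    sel = frame.ca_mask() & (frame.resids == resid)
    if not sel.any():
        raise ValueError(f"residue {resid} has no Calpha in this frame")
    return (float(frame.xyz[sel, 2].mean()) - ref.upper_p_z) * NM_TO_A
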