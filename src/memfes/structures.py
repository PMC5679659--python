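"""In-memory container for toy structures.

A :class:`ToyStructure` is a flat, array-backed record of atoms: enough to
compute collective variables, contacts, SASA and charge profiles, and to
round-trip through PDB/GRO text. It is deliberately much simpler than a full
topology — molecules are identified by residue index, species by a tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LEAFLET_NONE = "N"
LEAFLET_UPPER = "U"
LEAFLET_LOWER = "L"


@dataclass
class ToyStructure:
    """Array-of-atoms structure with species and leaflet tags.

    Attributes
    ----------
    names : (n,) str array — atom names (``CA``, ``P``, ``BD`` for beads).
    resids : (n,) int array — 1-based residue indices, contiguous per molecule.
    resnames : (n,) str array — residue names; for lipids this is the species.
    species : (n,) str array — species tag (PROT/BMP/CHOL/SM/DOPG/POPC/WAT/ION).
    xyz : (n, 3) float array — coordinates in nm.
    charges : (n,) float array — partial charges in e.
    radii : (n,) float array — vdW radii in nm.
    box : (3,) float array — orthorhombic box lengths in nm.
    leaflet : (n,) str array — 'U'/'L' for leaflet-assigned P atoms, else 'N'.
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    species: np.ndarray
    xyz: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    box: np.ndarray
    leaflet: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.leaflet is None:
            self.leaflet = np.full(n, LEAFLET_NONE, dtype="U1")
        for attr in ("resids", "resnames", "species", "xyz", "charges",
                     "radii", "leaflet"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length mismatch ({n} atoms)")
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    # -- selections ---------------------------------------------------------

    def mask_species(self, *tags: str) -> np.ndarray:
        return np.isin(self.species, list(tags))

    def select(self, mask: np.ndarray) -> "ToyStructure":
        return ToyStructure(
            names=self.names[mask], resids=self.resids[mask],
            resnames=self.resnames[mask], species=self.species[mask],
            xyz=self.xyz[mask], charges=self.charges[mask],
            radii=self.radii[mask], box=self.box.copy(),
            leaflet=self.leaflet[mask],
        )

    def protein(self) -> "ToyStructure":
        return self.select(self.mask_species("PROT"))

    def lipids(self) -> "ToyStructure":
        from .constants import LIPID_SPECIES
        return self.select(self.mask_species(*LIPID_SPECIES))

    def ca_mask(self) -> np.ndarray:
        return (self.species == "PROT") & (self.names == "CA")

    # -- rigid transforms ---------------------------------------------------

    def translated(self, shift) -> "ToyStructure":
        out = replace(self)
        out.xyz = self.xyz + np.asarray(shift, dtype=float)
        return out

    def rotated(self, R: np.ndarray, about=None) -> "ToyStructure":
        """Return a copy rotated by matrix ``R`` about ``about`` (default COM)."""
        R = np.asarray(R, dtype=float)
        pivot = self.xyz.mean(axis=0) if about is None else np.asarray(about)
        out = replace(self)
        out.xyz = (self.xyz - pivot) @ R.T + pivot
        return out


def concat(*parts: ToyStructure) -> ToyStructure:
    """Concatenate structures; the box of the first part wins."""
    return ToyStructure(
        names=np.concatenate([p.names for p in parts]),
        resids=np.concatenate([p.resids for p in parts]),
        resnames=np.concatenate([p.resnames for p in parts]),
        species=np.concatenate([p.species for p in parts]),
        xyz=np.concatenate([p.xyz for p in parts]),
        charges=np.concatenate([p.charges for p in parts]),
        radii=np.concatenate([p.radii for p in parts]),
        box=parts[0].box.copy(),
        leaflet=np.concatenate([p.leaflet for p in parts]),
    )


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (degrees)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
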