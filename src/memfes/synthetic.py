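"""Seeded generators for every input the pipeline consumes.

These builders stand in for MD-derived structures and trajectories: a rigid
130-residue pseudo-protein whose residue groupings define the long/short
orientation axes, two-leaflet bead membranes at requested molar fractions,
planted-contact trajectories that serve as an exact oracle for the contact
statistics, and slab/groove geometries for the dual-probe SASA analysis.

Everything is deterministic given its seed; none of it claims structural
realism beyond the statistical and geometric features the analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

from .constants import LIPID_SPECIES, MIL_SEQUENCE, SPECIES_CHARGE, SPECIES_RADIUS
from .structures import (LEAFLET_LOWER, LEAFLET_NONE, LEAFLET_UPPER,
                         ToyStructure, concat)

# Residue groups (1-based, inclusive ranges) defining the two orientation
# axes: each axis connects the Calpha COMs of its "pink" and "blue" groups.
LONG_AXIS_GROUPS = {
    "pink": [(1, 6), (19, 38), (55, 69), (93, 109), (123, 130)],
    "blue": [(7, 18), (39, 54), (70, 92), (110, 122)],
}
SHORT_AXIS_GROUPS = {
    "pink": [(1, 6), (13, 45), (75, 94), (124, 130)],
    "blue": [(7, 12), (46, 74), (95, 123)],
}

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _ranges_to_set(ranges: Sequence[tuple]) -> set:
    out: set = set()
    for lo, hi in ranges:
        out.update(range(lo, hi + 1))
    return out


def build_toy_protein(n_res: int = 130, seed: int = 0,
                      scale: float = 0.8, jitter: float = 0.22,
                      box=(12.0, 12.0, 12.0)) -> ToyStructure:
    """Rigid pseudo-protein with one Calpha per residue.

    Constructed so that, with the protein in its build frame, the long axis is
    exactly +z and the short axis exactly +x (both pink->blue COM vectors),
    the two axes are orthogonal, and the group COMs are > 1 nm apart. The
    membrane insertion loop (residues 59-65) is laid out contiguously; residue
    61 is the pocket-opening glycine used to label binding outcomes.

    Residue jitter is drawn from ``seed`` but re-centred within each group
    intersection class, so the axis construction is exact, not approximate.
    """
    if n_res < 130:
        raise ValueError("n_res must be >= 130 (axis groups reach residue 130)")
    rng = np.random.default_rng(seed)
    resids = np.arange(1, n_res + 1)

    long_pink = _ranges_to_set(LONG_AXIS_GROUPS["pink"])
    short_pink = _ranges_to_set(SHORT_AXIS_GROUPS["pink"])
    sL = np.array([1.0 if r in long_pink else -1.0 for r in resids])
    sS = np.array([1.0 if r in short_pink else -1.0 for r in resids])
    sL[130:] = 0.0  # residues beyond 130 belong to no axis group
    sS[130:] = 0.0

    in_groups = resids <= 130
    eps1 = sS[in_groups & (sL > 0)].mean() - sS[in_groups & (sL < 0)].mean()
    eps2 = sL[in_groups & (sS > 0)].mean() - sL[in_groups & (sS < 0)].mean()
    c = -scale * eps2 / 2.0
    d = -scale * eps1 / 2.0
    z_base = scale * sL + c * sS     # long-axis separation lives on z
    x_base = scale * sS + d * sL     # short-axis separation lives on x

    xyz = np.zeros((n_res, 3))
    xyz[:, 2] = z_base
    xyz[:, 0] = x_base

    jit = rng.normal(scale=jitter, size=(n_res, 3))
    # membrane insertion loop: contiguous 0.13 nm-spaced line on the surface
    mil = (resids >= 59) & (resids <= 65)
    jit[mil] = 0.0
    jit[mil, 1] = (resids[mil] - 62) * 0.13
    jit[mil, 0] = -0.35  # pushed outward so the loop sits on the surface
    # re-centre jitter within each (sL, sS) class so group COMs stay exact
    for key in set(zip(sL, sS)):
        m = (sL == key[0]) & (sS == key[1])
        jit[m] -= jit[m].mean(axis=0)
    xyz += jit

    resnames = np.full(n_res, "ALA", dtype="U4")
    for i, r in enumerate(range(59, 66)):
        resnames[r - 1] = THREE_LETTER[MIL_SEQUENCE[i]]
    return ToyStructure(
        names=np.full(n_res, "CA", dtype="U4"),
        resids=resids,
        resnames=resnames,
        species=np.full(n_res, "PROT", dtype="U4"),
        xyz=xyz,
        charges=np.zeros(n_res),
        radii=np.full(n_res, SPECIES_RADIUS["PROT"]),
        box=np.asarray(box, dtype=float),
    )


def largest_remainder_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer apportionment of ``n`` items to ``fractions`` (percent, sum 100)
    by the largest-remainder method; counts sum to ``n`` exactly."""
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 100.0) > 1e-9:
        raise ValueError("composition fractions must sum to 100")
    quota = fr * n / 100.0
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    short = n - counts.sum()
    order = np.argsort(-rem, kind="stable")
    counts[order[:short]] += 1
    return counts


def build_membrane_patch(composition: Sequence[float], n_lipids: int,
                         seed: int = 0, area_per_lipid: float = 0.65,
                         p_plane_z: float = 1.9,
                         box_z: float = 12.0) -> ToyStructure:
    """Two-leaflet bead membrane at the requested molar composition.

    ``composition`` gives mol% in the order BMP:CHOL:SM:DOPG:POPC. Each lipid
    is a head P atom (leaflet-tagged; absent for CHOL) plus one tail bead.
    Species counts follow largest-remainder rounding and sum to ``n_lipids``
    exactly; anionic species (BMP, DOPG) carry -1 e on the P atom.
    """
    if len(composition) != len(LIPID_SPECIES):
        raise ValueError(f"composition must list {len(LIPID_SPECIES)} fractions "
                         f"in the order {':'.join(LIPID_SPECIES)}")
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    counts = largest_remainder_counts(composition, n_lipids)
    rng = np.random.default_rng(seed)
    species_list = np.repeat(np.array(LIPID_SPECIES), counts)
    rng.shuffle(species_list)

    n_leaf = n_lipids // 2
    side = int(np.ceil(np.sqrt(n_leaf)))
    lxy = side * np.sqrt(area_per_lipid)
    spacing = np.sqrt(area_per_lipid)

    names, resids, resnames, species, xyz = [], [], [], [], []
    charges, radii, leaflet = [], [], []
    resid = 0
    for i, sp in enumerate(species_list):
        resid += 1
        upper = i < n_leaf
        j = i if upper else i - n_leaf
        x = (j % side + 0.5) * spacing
        y = (j // side + 0.5) * spacing
        sgn = 1.0 if upper else -1.0
        tag = LEAFLET_UPPER if upper else LEAFLET_LOWER
        if sp != "CHOL":
            names.append("P")
            resids.append(resid)
            resnames.append(sp)
            species.append(sp)
            xyz.append((x, y, sgn * p_plane_z))
            charges.append(SPECIES_CHARGE[sp])
            radii.append(0.20)
            leaflet.append(tag)
        bead_z = sgn * (1.2 if sp == "CHOL" else 0.8)
        names.append("BD")
        resids.append(resid)
        resnames.append(sp)
        species.append(sp)
        xyz.append((x, y, bead_z))
        charges.append(0.0)
        radii.append(SPECIES_RADIUS[sp])
        leaflet.append(LEAFLET_NONE)

    return ToyStructure(
        names=np.array(names, dtype="U4"),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype="U4"),
        species=np.array(species, dtype="U4"),
        xyz=np.array(xyz),
        charges=np.array(charges),
        radii=np.array(radii),
        box=np.array([lxy, lxy, box_z]),
        leaflet=np.array(leaflet, dtype="U1"),
    )


def species_counts(struct: ToyStructure) -> Dict[str, int]:
    """Lipid molecule counts per species (one residue per lipid)."""
    out: Dict[str, int] = {}
    lip = struct.lipids()
    for sp in LIPID_SPECIES:
        out[sp] = len(np.unique(lip.resids[lip.species == sp]))
    return out


# -- planted-contact trajectories ------------------------------------------

@dataclass
class PlantedTrajectory:
    """Frame sequence with exactly known per-residue contact statistics."""

    base: ToyStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3) nm
    spec: Mapping[int, Mapping[str, float]]
    cutoff: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def structure_at(self, i: int) -> ToyStructure:
        s = self.base.select(np.ones(self.base.n_atoms, dtype=bool))
        s.xyz = self.frames[i].copy()
        return s


def validate_planted_spec(spec: Mapping[int, Mapping[str, float]]) -> None:
    for r, probs in spec.items():
        if not probs:
            raise ValueError(f"residue {r}: at least one species required")
        for sp, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"residue {r}, species {sp}: "
                                 f"probability {p} outside [0, 1]")
        if sum(probs.values()) > 1.0 + 1e-12:
            raise ValueError(f"residue {r}: probabilities sum beyond 1")


def emit_planted_trajectory(spec: Mapping[int, Mapping[str, float]],
                            n_frames: int, cutoff: float = 0.4,
                            seed: int = 0) -> PlantedTrajectory:
    """Trajectory in which residue r touches a lipid of species s with the
    planted per-frame probability.

    Residues are placed on a well-separated grid (3 cutoffs apart) so that a
    bead planted for one residue can never register as a contact of another;
    each (residue, species) pair owns a dedicated lipid bead that sits at
    0.75 cutoff when in contact and is parked far away otherwise. Per frame
    and residue, the contacting species is drawn categorically from the
    planted probabilities (no contact with the leftover probability), so the
    empirical contact frequencies converge to the spec as frames accumulate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    validate_planted_spec(spec)
    rng = np.random.default_rng(seed)
    residues = sorted(spec)
    pitch = 3.0 * cutoff

    names, resids, resnames, sp_tags, xyz = [], [], [], [], []
    charges, radii = [], []
    pair_atom: Dict[tuple, int] = {}
    for k, r in enumerate(residues):
        names.append("CA"); resids.append(r); resnames.append("ALA")
        sp_tags.append("PROT")
        xyz.append((k * pitch, 0.0, 0.0))
        charges.append(0.0); radii.append(SPECIES_RADIUS["PROT"])
    next_resid = max(residues) + 1
    for k, r in enumerate(residues):
        for sp in sorted(spec[r]):
            pair_atom[(r, sp)] = len(names)
            names.append("BD"); resids.append(next_resid); resnames.append(sp)
            sp_tags.append(sp)
            xyz.append((k * pitch, 50.0 + next_resid, 0.0))  # parked
            charges.append(SPECIES_CHARGE.get(sp, 0.0))
            radii.append(SPECIES_RADIUS.get(sp, 0.25))
            next_resid += 1

    base = ToyStructure(
        names=np.array(names, dtype="U4"), resids=np.array(resids),
        resnames=np.array(resnames, dtype="U4"),
        species=np.array(sp_tags, dtype="U4"), xyz=np.array(xyz),
        charges=np.array(charges), radii=np.array(radii),
        box=np.array([pitch * max(len(residues), 1) + 200.0, 200.0, 200.0]),
    )

    frames = np.repeat(base.xyz[None, :, :], n_frames, axis=0)
    for k, r in enumerate(residues):
        species = sorted(spec[r])
        probs = np.array([spec[r][sp] for sp in species])
        edges = np.concatenate([[0.0], np.cumsum(probs)])
        u = rng.random(n_frames)
        theta = rng.random(n_frames) * 2 * np.pi
        for j, sp in enumerate(species):
            hit = (u >= edges[j]) & (u < edges[j + 1])
            a = pair_atom[(r, sp)]
            offs = 0.75 * cutoff * np.stack(
                [np.cos(theta[hit]), np.sin(theta[hit]),
                 np.zeros(hit.sum())], axis=-1)
            frames[hit, a, :] = base.xyz[k] + offs
    return PlantedTrajectory(base=base, frames=frames, spec=dict(spec),
                             cutoff=cutoff)


# -- SASA test geometries ---------------------------------------------------

def build_groove_surface(gap_width: float, depth: float = 0.5,
                         atom_radius: float = 0.14,
                         extent=(4.0, 2.0)) -> ToyStructure:
    """Flat atom slab with a rectangular groove running along y.

    ``gap_width`` is the surface-to-surface distance between the groove walls
    (nm); floor atoms (named ``FL``) line the bottom of the groove at
    ``depth`` below the top surface. ``gap_width = 0`` returns a plain flat
    slab whose top-layer atoms are tagged as the floor. Lattice spacing
    equals ``atom_radius`` so the solid is watertight for any probe.
    """
    if gap_width < 0:
        raise ValueError("gap_width must be >= 0")
    r = atom_radius
    s = r
    lx, ly = extent
    xs = np.arange(0.5 * s, lx, s)
    ys = np.arange(0.5 * s, ly, s)
    cx = lx / 2.0
    half = gap_width / 2.0 + r  # wall-centre offset giving the requested gap

    pts, tags = [], []
    if gap_width == 0.0:
        for x in xs:
            for y in ys:
                pts.append((x, y, 0.0)); tags.append("FL")
        base_z0 = 0.0
    else:
        for x in xs:
            if abs(x - cx) < half - 1e-9:
                continue
            for y in ys:
                pts.append((x, y, 0.0)); tags.append("SL")
        zs = np.arange(-s, -depth, -s)
        for wall_x in (cx - half, cx + half):
            for z in zs:
                for y in ys:
                    pts.append((wall_x, y, z)); tags.append("SL")
        floor_xs = xs[(xs > cx - half - 1e-9) & (xs < cx + half + 1e-9)]
        if len(floor_xs) == 0:
            floor_xs = np.array([cx])
        for x in floor_xs:
            for y in ys:
                pts.append((x, y, -depth)); tags.append("FL")
        base_z0 = -depth
    # full base layers seal the solid from below: accessibility is a purely
    # local test, so an open underside would count as exposed surface
    for dz in (1, 2):
        for x in xs:
            for y in ys:
                pts.append((x, y, base_z0 - dz * s)); tags.append("SL")

    n = len(pts)
    return ToyStructure(
        names=np.array(tags, dtype="U4"),
        resids=np.arange(1, n + 1),
        resnames=np.full(n, "SLB", dtype="U4"),
        species=np.full(n, "SLAB", dtype="U4"),
        xyz=np.array(pts),
        charges=np.zeros(n),
        radii=np.full(n, r),
        box=np.array([lx, ly, 50.0]),
    )


# -- posing -----------------------------------------------------------------

def pose_protein(protein: ToyStructure, phi_deg: float, min_zr: float,
                 upper_p_z: float, theta_deg: float = 90.0) -> ToyStructure:
    """Rigidly pose the protein at orientation (theta, phi) and insertion depth.

    The long axis is placed at ``theta_deg`` from the membrane normal (+z),
    the short axis at ``phi_deg`` (both in the x-z plane of the lab frame),
    and the protein is translated so the lowest Calpha sits at ``min_zr``
    Angstrom relative to the upper-leaflet P plane at ``upper_p_z`` nm.
    """
    from .cv import protein_axes  # deferred to avoid an import cycle
    long_ax, short_ax = protein_axes(protein)
    tl = np.deg2rad(theta_deg)
    tp = np.deg2rad(phi_deg)
    target_long = np.array([np.sin(tl), 0.0, np.cos(tl)])
    # the short axis must be perpendicular to the long one; build it in the
    # long-perpendicular plane so its angle to +z is exactly phi
    sin_t = np.sin(tl)
    if abs(np.cos(tp)) > sin_t + 1e-12:
        raise ValueError("phi unreachable at this theta: |cos phi| > sin theta "
                         "with orthogonal axes")
    u = np.array([0.0, 0.0, 1.0]) - np.cos(tl) * target_long
    u /= np.linalg.norm(u)                      # in-plane direction, u.z = sin(theta)
    v = np.cross(target_long, u)
    cos_perp = np.clip(np.cos(tp) / sin_t, -1.0, 1.0)
    target_short = cos_perp * u + np.sqrt(1.0 - cos_perp ** 2) * v
    src3 = np.cross(long_ax, short_ax)
    tgt3 = np.cross(target_long, target_short)
    S = np.stack([long_ax, short_ax - short_ax @ long_ax * long_ax, src3])
    S[1] /= np.linalg.norm(S[1])
    T = np.stack([target_long, target_short, tgt3])
    R = T.T @ S
    posed = protein.rotated(R)
    ca = posed.xyz[posed.ca_mask()]
    shift_z = (upper_p_z + min_zr / 10.0) - ca[:, 2].min()
    return posed.translated((0.0, 0.0, shift_z))
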