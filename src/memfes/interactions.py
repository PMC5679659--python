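"""Per-residue lipid statistics: normalized contact frequency (NCF),
dual-probe solvent-accessible surface area, and electrostatic profiles.

NCF of residue r is the fraction of its per-frame lipid contacts that are
with BMP: values near 1 mark specific BMP contacts, near 0 unspecific or
absent ones. The SASA-ratio compares membrane-surface accessibility to a
loop-sized probe (0.58 nm, the minimal sphere bounding the 694 Da membrane
insertion loop) against a water-sized probe (0.14 nm): ~1 means the surface
presents lipids to the loop as freely as to water, ~0 means lipids are only
reachable through crevices narrower than the loop. The electrostatic profile
double-integrates the charge density along the membrane normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import (EPS0, FARADAY_KJ_PER_MOL_V, LIPID_SPECIES,
                        RESIDUE_MASS_DA)
from .structures import ToyStructure


# -- contacts and NCF -------------------------------------------------------

@dataclass
class ContactCounts:
    """Aggregated (residue, species) -> per-frame-binary contact counts."""

    counts: Dict[tuple, int] = field(default_factory=dict)
    n_frames: int = 0

    def add(self, other: "ContactCounts") -> "ContactCounts":
        for key, v in other.counts.items():
            self.counts[key] = self.counts.get(key, 0) + v
        self.n_frames += other.n_frames
        return self

    def residue_total(self, resid: int) -> int:
        return sum(v for (r, _), v in self.counts.items() if r == resid)


def residue_lipid_contacts(frame: ToyStructure, cutoff: float = 0.4,
                           species: Sequence[str] = LIPID_SPECIES
                           ) -> ContactCounts:
    """One frame's contact increment: residue r contacts species s iff the
    minimum atom distance between r and any lipid of s is <= cutoff (nm)."""
    out = ContactCounts(n_frames=1)
    prot = frame.protein()
    if prot.n_atoms == 0:
        raise ValueError("frame has no protein atoms")
    trees = {}
    for sp in species:
        m = frame.species == sp
        if m.any():
            trees[sp] = cKDTree(frame.xyz[m])
    if not trees:
        return out
    for resid in np.unique(prot.resids):
        pts = prot.xyz[prot.resids == resid]
        for sp, tree in trees.items():
            d, _ = tree.query(pts, k=1)
            if d.min() <= cutoff:
                out.counts[(int(resid), sp)] = 1
    return out


def accumulate_contacts(frames: Iterable[ToyStructure],
                        cutoff: float = 0.4) -> ContactCounts:
    total = ContactCounts()
    for f in frames:
        total.add(residue_lipid_contacts(f, cutoff))
    return total


@dataclass
class NCFProfile:
    """Residue -> NCF in [0, 1]; NaN where the residue saw no lipid at all."""

    residues: np.ndarray
    ncf: np.ndarray
    flag_threshold: float = 0.4

    def flagged(self) -> np.ndarray:
        """Residues displayed as BMP-specific (NCF above the threshold)."""
        ok = np.isfinite(self.ncf) & (self.ncf > self.flag_threshold)
        return self.residues[ok]


def ncf_profile(counts: ContactCounts, target: str = "BMP") -> NCFProfile:
    """ncf(r) = counts(r, target) / sum_s counts(r, s); undefined (NaN) when
    the residue made no lipid contact in any frame."""
    residues = sorted({r for (r, _) in counts.counts})
    vals = []
    for r in residues:
        tot = counts.residue_total(r)
        if tot == 0:
            vals.append(np.nan)
        else:
            vals.append(counts.counts.get((r, target), 0) / tot)
    return NCFProfile(residues=np.array(residues, dtype=int),
                      ncf=np.array(vals, dtype=float))


def ncf_across_systems(profiles: Sequence[NCFProfile]):
    """Mean and standard deviation of NCF across systems, residue-aligned."""
    residues = sorted(set().union(*[set(p.residues.tolist()) for p in profiles]))
    mat = np.full((len(profiles), len(residues)), np.nan)
    for i, p in enumerate(profiles):
        lookup = dict(zip(p.residues.tolist(), p.ncf))
        for j, r in enumerate(residues):
            mat[i, j] = lookup.get(r, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return (np.array(residues), np.nanmean(mat, axis=0),
                np.nanstd(mat, axis=0))


# -- probe sizing -----------------------------------------------------------

def probe_radius_from_mass(mass_da: float) -> float:
    """Minimal bounding-sphere radius of a protein of mass M (Da), nm:
    R_min = 0.066 M^(1/3). At the insertion loop's 694 Da this gives 0.58 nm."""
    if mass_da < 0:
        raise ValueError("mass must be >= 0")
    return 0.066 * mass_da ** (1.0 / 3.0)


def residue_set_mass(sequence: str) -> float:
    """Total average residue (amino acid minus water) mass of a one-letter
    sequence, Da."""
    total = 0.0
    for ch in sequence:
        try:
            total += RESIDUE_MASS_DA[ch.upper()]
        except KeyError:
            raise ValueError(f"unknown residue code {ch!r}") from None
    return total


# -- Shrake-Rupley SASA -----------------------------------------------------

@dataclass
class SASAConfig:
    probe_radius: float = 0.14     # nm
    n_points: int = 960
    periodic_xy: bool = False
    #: rotate the quadrature point set per atom (seeded, deterministic);
    #: decoheres the per-atom quantisation error so summed areas over many
    #: atoms are unbiased even when individual exposed caps are tiny
    rotate_points: bool = True
    orientation_seed: int = 1234

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 32:
            raise ValueError("need at least 32 sphere points")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=-1)


def sasa(struct: ToyStructure, cfg: SASAConfig = None,
         subset: np.ndarray = None) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible areas (nm^2).

    Only ``subset`` atoms' areas are returned, but *all* atoms occlude. With
    ``cfg.periodic_xy`` the eight in-plane periodic images occlude as well
    (slab geometries). A test point on atom i's expanded sphere (radius
    r_i + probe) is accessible iff it lies outside every other atom's
    expanded sphere.
    """
    cfg = cfg or SASAConfig()
    if np.any(~np.isfinite(struct.radii)) or np.any(struct.radii <= 0):
        raise ValueError("every atom needs a positive vdW radius")
    n = struct.n_atoms
    subset = np.arange(n) if subset is None else np.flatnonzero(subset) \
        if subset.dtype == bool else np.asarray(subset)
    R = struct.radii + cfg.probe_radius
    occ_xyz = [struct.xyz]
    occ_owner = [np.arange(n)]
    occ_image = [np.zeros(n, dtype=int)]
    if cfg.periodic_xy:
        lx, ly = struct.box[0], struct.box[1]
        img = 1
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                occ_xyz.append(struct.xyz + np.array([dx * lx, dy * ly, 0.0]))
                occ_owner.append(np.arange(n))
                occ_image.append(np.full(n, img, dtype=int))
                img += 1
    occ_xyz = np.concatenate(occ_xyz)
    occ_owner = np.concatenate(occ_owner)
    occ_image = np.concatenate(occ_image)
    occ_R = R[occ_owner]
    tree = cKDTree(occ_xyz)
    dirs = _sphere_points(cfg.n_points)
    rmax = occ_R.max()
    rng = np.random.default_rng(cfg.orientation_seed)

    areas = np.empty(len(subset))
    for k, i in enumerate(subset):
        if cfg.rotate_points:
            Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
            pts = struct.xyz[i] + R[i] * (dirs @ Q.T)
        else:
            pts = struct.xyz[i] + R[i] * dirs
        nb = tree.query_ball_point(struct.xyz[i], R[i] + rmax)
        nb = [j for j in nb if not (occ_owner[j] == i and occ_image[j] == 0)]
        if nb:
            d2 = ((pts[:, None, :] - occ_xyz[nb][None, :, :]) ** 2).sum(-1)
            exposed = (d2 > (occ_R[nb] ** 2)[None, :] - 1e-12).all(axis=1)
        else:
            exposed = np.ones(cfg.n_points, dtype=bool)
        areas[k] = 4.0 * np.pi * R[i] ** 2 * exposed.mean()
    return areas


def sasa_ratio(frames: Iterable[ToyStructure], subset_of=None,
               probes: tuple = (0.14, 0.58), n_points: int = 960,
               periodic_xy: bool = True):
    """Ensemble mean +- sd of (subset SASA at the large probe) / (at the
    small probe). ``subset_of`` maps a frame to a boolean atom mask (default:
    all atoms). Frames with zero small-probe area are excluded with a warning.
    """
    small, large = sorted(probes)
    ratios = []
    for idx, frame in enumerate(frames):
        mask = None if subset_of is None else subset_of(frame)
        a_small = sasa(frame, SASAConfig(small, n_points, periodic_xy),
                       mask).sum()
        a_large = sasa(frame, SASAConfig(large, n_points, periodic_xy),
                       mask).sum()
        if a_small <= 0:
            warnings.warn(f"frame {idx}: zero small-probe area, excluded")
            continue
        ratios.append(a_large / a_small)
    if not ratios:
        raise ValueError("no usable frames for the SASA ratio")
    r = np.asarray(ratios)
    return float(r.mean()), float(r.std(ddof=0))


# -- electrostatics ---------------------------------------------------------

@dataclass
class PotentialProfile:
    z_centers: np.ndarray          # nm
    charge_density: np.ndarray     # e/nm^3, frame mean
    potential: np.ndarray          # kJ/mol/e, frame mean; 0 at both edges
    potential_se: np.ndarray       # standard error across frames

    @property
    def potential_volts(self) -> np.ndarray:
        return self.potential / FARADAY_KJ_PER_MOL_V

    @property
    def potential_se_volts(self) -> np.ndarray:
        return self.potential_se / FARADAY_KJ_PER_MOL_V


def electrostatic_profile(frames: Iterable[ToyStructure], n_bins: int = 200,
                          center_on_membrane: bool = True,
                          symmetrize: bool = True) -> PotentialProfile:
    """Charge density -> field -> potential along z, frame-averaged.

    Per frame the charge density rho(z) is binned (optionally after centring
    the lipid COM at the box midplane), integrated once to the field
    E = (1/eps0) int rho dz and again to psi = -int E dz with psi(0) = 0.

    With ``symmetrize`` (the default, appropriate for bilayers whose two
    leaflets are statistically equivalent) rho is mirror-averaged over the
    two box halves first, which also pins psi to zero at *both* edges.
    Disable it for intrinsically asymmetric charge layouts. Non-neutral
    frames are integrated anyway but flagged, since their field cannot close.
    """
    psis, rhos = [], []
    z_edges = None
    for frame in frames:
        lz = frame.box[2]
        area = frame.box[0] * frame.box[1]
        if z_edges is None:
            z_edges = np.linspace(0.0, lz, n_bins + 1)
        dz = z_edges[1] - z_edges[0]
        z = frame.xyz[:, 2].copy()
        if center_on_membrane:
            lip = frame.mask_species(*LIPID_SPECIES)
            ref = frame.xyz[lip, 2].mean() if lip.any() else z.mean()
            z += lz / 2.0 - ref
        if abs(frame.charges.sum()) > 1e-9:
            warnings.warn("frame is not charge-neutral; the field will not "
                          "close at the box edges")
        hist, _ = np.histogram(np.clip(z, 0, lz - 1e-12), bins=z_edges,
                               weights=frame.charges)
        rho = hist / (area * dz)
        if symmetrize:
            rho = 0.5 * (rho + rho[::-1])      # mirror average of box halves
        # midpoint rule: field at bin centers (keeps the discrete field
        # exactly antisymmetric for a mirror-symmetric density)
        E = (np.cumsum(rho) - 0.5 * rho) * dz / EPS0
        psi = -np.concatenate([[0.0], np.cumsum(E) * dz])
        if symmetrize:
            # a symmetric neutral density closes exactly; remove the residual
            # discretisation ramp so psi(0) = psi(L) = 0 by construction
            psi -= np.linspace(0.0, psi[-1], len(psi))
        centers = 0.5 * (z_edges[:-1] + z_edges[1:])
        psis.append(0.5 * (psi[:-1] + psi[1:]))
        rhos.append(rho)
    if not psis:
        raise ValueError("no frames given")
    P = np.asarray(psis)
    return PotentialProfile(
        z_centers=0.5 * (z_edges[:-1] + z_edges[1:]),
        charge_density=np.asarray(rhos).mean(axis=0),
        potential=P.mean(axis=0),
        potential_se=P.std(axis=0, ddof=0) / np.sqrt(len(psis)),
    )
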