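"""Binding thermodynamics derived from PMFs: per-orientation binding free
energies, the orientation-interconversion (rocking) barrier, and the
membrane-binding thermodynamic cycle for the cholesterol-binding free energy.

Conventions. A binding mode is a rectangle in (z, phi): an insertion-depth
band times an orientation band (Prone phi > 140 deg, Supine phi < 40 deg).
The per-mode association free energy compares the Boltzmann weight inside
the mode region against bulk solvent, with the bulk weight rescaled to the
mode's phi-extent and a reference z-slab (1 Angstrom by default) so that
dG is a per-orientation association free energy; the slab width is exposed
because the convention, not the physics, fixes it. The cycle quantity
ddG(min z_r) = dG_chol-bound(min z_r) - dG_apo(min z_r) measures how membrane
binding changes the protein's cholesterol-binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from .constants import KT_310
from .fes import PMFGrid, WeightedSamples


@dataclass(frozen=True)
class ModeDefinition:
    name: str
    phi_interval: tuple       # deg
    z_interval: tuple         # Angstrom

    def __post_init__(self):
        if self.phi_interval[0] >= self.phi_interval[1] \
                or self.z_interval[0] >= self.z_interval[1]:
            raise ValueError("mode intervals must be non-empty")


PRONE = ModeDefinition("Prone", (140.0, 180.0), (-10.0, 10.0))
SUPINE = ModeDefinition("Supine", (0.0, 40.0), (-10.0, 10.0))
MEMBRANE_ASSOCIATED = ModeDefinition("MembraneAssociated", (0.0, 180.0),
                                     (-10.0, 10.0))
DEFAULT_MODES = (PRONE, SUPINE, MEMBRANE_ASSOCIATED)


@dataclass
class DDGCurve:
    """Pointwise thermodynamic-cycle difference on a min z_r grid."""

    z_centers: np.ndarray
    ddg: np.ndarray           # kJ/mol; NaN where either input is undefined
    error: np.ndarray | None = None


def _mode_and_bulk_weights_grid(grid: PMFGrid, mode: ModeDefinition,
                                bulk_slab: tuple, kT: float):
    names = [n.lower() for n in grid.names]
    try:
        zi = [i for i, n in enumerate(names) if n in ("z", "minzr", "min_zr")][0]
        pi = names.index("phi")
    except (IndexError, ValueError):
        raise ValueError("mode free energy needs a (z, phi) PMF grid")
    zc, pc = grid.centers(zi), grid.centers(pi)
    dz = np.diff(grid.axes[zi][1]).mean()
    dp = np.diff(grid.axes[pi][1]).mean()
    F = np.moveaxis(grid.F, (zi, pi), (0, 1))
    E = None
    if grid.error is not None:
        E = np.moveaxis(grid.error, (zi, pi), (0, 1))
    w = np.where(np.isfinite(F), np.exp(-np.nan_to_num(F) / kT), 0.0) * dz * dp

    in_mode = np.ix_((zc >= mode.z_interval[0]) & (zc <= mode.z_interval[1]),
                     (pc >= mode.phi_interval[0]) & (pc <= mode.phi_interval[1]))
    in_bulk = (zc >= bulk_slab[0]) & (zc <= bulk_slab[1])
    w_mode = w[in_mode]
    w_bulk = w[in_bulk, :]
    area_bulk = np.count_nonzero(w_bulk) * dz * dp
    return w_mode, w_bulk, area_bulk, E, in_mode, in_bulk


def mode_free_energy(source, mode: ModeDefinition, bulk_slab: tuple,
                     kT: float = KT_310, z_slab_width: float = 1.0):
    """Per-mode association free energy dG +- err (kJ/mol).

    dG = -kT ln( W_mode / (rho_bulk * phi_extent(mode) * z_slab_width) ),
    where W_mode is the Boltzmann weight in the mode rectangle and rho_bulk
    the bulk weight density per (Angstrom x degree). Accepts a (z, phi)
    :class:`PMFGrid` (errors propagated from its error grid when present) or
    raw :class:`WeightedSamples`.
    """
    phi_extent = mode.phi_interval[1] - mode.phi_interval[0]
    if isinstance(source, PMFGrid):
        w_mode, w_bulk, area_bulk, E, in_mode, in_bulk = \
            _mode_and_bulk_weights_grid(source, mode, bulk_slab, kT)
        W_mode = w_mode.sum()
        W_bulk = w_bulk.sum()
        if W_mode <= 0:
            raise ValueError(f"mode {mode.name} region is unsampled")
        if W_bulk <= 0 or area_bulk <= 0:
            raise ValueError("bulk reference slab is unsampled")
        rho_bulk = W_bulk / area_bulk
        dg = -kT * np.log(W_mode / (rho_bulk * phi_extent * z_slab_width))
        err = np.nan
        if E is not None:
            em = E[in_mode]
            eb = E[in_bulk, :]
            err = float(np.sqrt(
                _weighted_err(w_mode, em) ** 2 + _weighted_err(w_bulk, eb) ** 2))
        return float(dg), err
    if isinstance(source, WeightedSamples):
        z, phi = source.z, source.cvs[:, 2]
        a = np.exp(source.log_weight - source.log_weight.max())
        m = ((z >= mode.z_interval[0]) & (z <= mode.z_interval[1])
             & (phi >= mode.phi_interval[0]) & (phi <= mode.phi_interval[1]))
        b = (z >= bulk_slab[0]) & (z <= bulk_slab[1])
        if not m.any():
            raise ValueError(f"mode {mode.name} region is unsampled")
        if not b.any():
            raise ValueError("bulk reference slab is unsampled")
        rho_bulk = a[b].sum() / ((bulk_slab[1] - bulk_slab[0]) * 180.0)
        dg = -kT * np.log(a[m].sum() / (rho_bulk * phi_extent * z_slab_width))
        return float(dg), np.nan
    raise TypeError("source must be a PMFGrid or WeightedSamples")


def _weighted_err(w: np.ndarray, e: np.ndarray) -> float:
    """Weight-averaged pointwise error of a -kT ln(sum w) aggregate."""
    ok = np.isfinite(e) & (w > 0)
    if not ok.any():
        return 0.0
    return float((w[ok] * e[ok]).sum() / w[ok].sum())


def interconversion_barrier(grid: PMFGrid,
                            prone: ModeDefinition = PRONE,
                            supine: ModeDefinition = SUPINE,
                            assoc_band: tuple = (-10.0, 10.0),
                            kT: float = KT_310) -> float:
    """Rocking barrier between the two orientation basins (kJ/mol).

    The lowest phi-crossing without membrane detachment: over z-rows inside
    the membrane-associated band, the smallest of [max F along phi between the
    basin minima], measured from the shallower basin minimum. Undefined (a
    ValueError) when either basin has no sampled bins.
    """
    names = [n.lower() for n in grid.names]
    zi = [i for i, n in enumerate(names) if n in ("z", "minzr", "min_zr")][0]
    pi = names.index("phi")
    zc, pc = grid.centers(zi), grid.centers(pi)
    F = np.moveaxis(grid.F, (zi, pi), (0, 1))
    band = (zc >= assoc_band[0]) & (zc <= assoc_band[1])
    Fb = F[band, :]

    minima = {}
    for m in (prone, supine):
        zin = (zc[band] >= m.z_interval[0]) & (zc[band] <= m.z_interval[1])
        pin = (pc >= m.phi_interval[0]) & (pc <= m.phi_interval[1])
        sub = Fb[np.ix_(zin, pin)]
        if not np.isfinite(sub).any():
            raise ValueError(f"basin {m.name} absent from the PMF; "
                             "barrier undefined")
        flat = np.nanargmin(np.where(np.isfinite(sub), sub, np.inf))
        ii, jj = np.unravel_index(flat, sub.shape)
        minima[m.name] = (float(sub[ii, jj]), pc[pin][jj])
    f_prone, phi_p = minima[prone.name]
    f_supine, phi_s = minima[supine.name]
    lo_phi, hi_phi = sorted((phi_p, phi_s))
    seg = (pc >= lo_phi) & (pc <= hi_phi)

    best = np.inf
    for row in Fb:
        vals = row[seg]
        if not np.isfinite(vals).all():
            continue  # a hole in the path: cannot cross through this row
        best = min(best, float(vals.max()))
    if not np.isfinite(best):
        raise ValueError("no continuous phi-path inside the associated band")
    return best - max(f_prone, f_supine)


def landscape_barrier(landscape, prone_center, supine_center,
                      dz: float = 0.2, dphi: float = 0.5,
                      pad: float = 4.0) -> float:
    """Analytic-landscape counterpart of :func:`interconversion_barrier`,
    evaluated on a fine grid; ground truth for recovery tests."""
    z_lo = min(prone_center[0], supine_center[0]) - pad
    z_hi = max(prone_center[0], supine_center[0]) + pad
    zs = np.arange(z_lo, z_hi + 1e-9, dz)
    lo_phi, hi_phi = sorted((prone_center[1], supine_center[1]))
    ps = np.arange(lo_phi, hi_phi + 1e-9, dphi)
    Z, P = np.meshgrid(zs, ps, indexing="ij")
    U = landscape.energy(np.stack([Z.ravel(), P.ravel()], axis=-1)) \
        .reshape(Z.shape)
    mins = []
    for center in (prone_center, supine_center):
        near = (np.abs(Z - center[0]) <= pad) & (np.abs(P - center[1]) <= 30.0)
        mins.append(U[near].min())
    saddle = U.max(axis=1).min()
    return float(saddle - max(mins))


def ddg_chol_binding(pmf_chol: PMFGrid, pmf_apo: PMFGrid) -> DDGCurve:
    """Cycle closure: ddG(min z_r) = dG_chol-bound - dG_apo, pointwise.

    Both inputs must be 1D PMFs on identical min z_r grids sharing the bulk
    reference convention; the curve is defined only where both are.
    """
    if len(pmf_chol.axes) != 1 or len(pmf_apo.axes) != 1:
        raise ValueError("ddg expects 1D PMFs over min z_r")
    e1, e2 = pmf_chol.axes[0][1], pmf_apo.axes[0][1]
    if len(e1) != len(e2) or not np.allclose(e1, e2):
        raise ValueError("PMF grids do not match; rebin to a common grid")
    ddg = pmf_chol.F - pmf_apo.F
    err = None
    if pmf_chol.error is not None and pmf_apo.error is not None:
        err = np.sqrt(pmf_chol.error ** 2 + pmf_apo.error ** 2)
    return DDGCurve(z_centers=pmf_chol.centers(0), ddg=ddg, error=err)


# -- summary table ----------------------------------------------------------

@dataclass
class BindingReport:
    """Per-mode association free energies for one system/state."""

    system: str
    state: str                     # 'chol-bound' or 'apo'
    dg: Dict[str, float]
    err: Dict[str, float]

    def __post_init__(self):
        if any(np.isfinite(e) and e < 0 for e in self.err.values()):
            raise ValueError("errors must be >= 0")


def table1_report(pmfs: Mapping[tuple, PMFGrid],
                  modes=DEFAULT_MODES,
                  bulk_slab: tuple = None,
                  kT: float = KT_310) -> pd.DataFrame:
    """Assemble the binding-summary table: one row per system, one
    (state, mode) column pair per free-energy entry, values 'dG +- err'.

    ``pmfs`` maps (system, state) to a (z, phi) PMF grid.
    """
    reports: List[BindingReport] = []
    for (system, state), grid in pmfs.items():
        names = [n.lower() for n in grid.names]
        zi = [i for i, n in enumerate(names)
              if n in ("z", "minzr", "min_zr")][0]
        slab = bulk_slab
        if slab is None:
            z_hi = grid.axes[zi][1][-1]
            slab = (z_hi - 10.0, z_hi)
        dg, err = {}, {}
        for mode in modes:
            dg[mode.name], err[mode.name] = mode_free_energy(
                grid, mode, slab, kT)
        reports.append(BindingReport(system=str(system), state=str(state),
                                     dg=dg, err=err))
    rows = {}
    for r in reports:
        row = rows.setdefault(r.system, {})
        for name in r.dg:
            row[(r.state, name)] = (f"{r.dg[name]:.1f}"
                                    + ("" if not np.isfinite(r.err[name])
                                       else f"±{r.err[name]:.1f}"))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "system"
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["state", "mode"])
    return df.sort_index(axis=1)
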