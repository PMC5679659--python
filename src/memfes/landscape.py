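"""Analytic free-energy landscapes used as ground truth by the toy sampler.

The default two-basin surface over (z, phi) mimics the topology of a
peripheral protein binding a membrane in two orientations: a deep, narrow
*Prone* basin (pocket facing the membrane, inserted below the phosphate
plane, phi near 160 deg), a slightly deeper but wider *Supine* basin (phi
near 20 deg, shallow insertion), and a membrane-associated trough connecting
them along phi so that the protein can "rock" between the orientations
without detaching. Far from the membrane (large z) the surface decays to
zero, which defines the bulk reference.

Coordinates: z in Angstrom (signed, origin at the upper-leaflet phosphate
plane), angles in degrees. Energies in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class Basin:
    """A Gaussian well. ``center``/``width`` have one entry per landscape dim;
    an entry of ``None`` makes the well flat (inactive) along that dimension,
    which is how the membrane-associated trough (z-only) is expressed.

    ``depth`` is the *configured* well depth (< 0, kJ/mol); ``amplitude`` is
    the prefactor actually used, set during calibration so the realised
    minimum matches ``depth`` despite overlap with other terms.
    """

    center: tuple
    depth: float
    width: tuple
    amplitude: float = field(default=None)  # type: ignore[assignment]

    def factor(self, pts: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian factor at points (n, dims)."""
        arg = np.zeros(pts.shape[0])
        for d, (c, w) in enumerate(zip(self.center, self.width)):
            if c is None or w is None:
                continue
            arg += (pts[:, d] - c) ** 2 / (2.0 * w * w)
        return np.exp(-arg)


class AnalyticLandscape:
    """Sum-of-Gaussian-wells potential with analytic gradient.

    Invariants: finite everywhere, decays to ~0 in the designated bulk region,
    and each basin's realised minimum equals its configured depth to within
    0.1 kJ/mol (enforced by :func:`build_landscape`).
    """

    def __init__(self, basins: Sequence[Basin], domain: Sequence[tuple],
                 names: Sequence[str] | None = None):
        self.basins = list(basins)
        self.domain = [tuple(map(float, d)) for d in domain]
        self.dims = len(self.domain)
        self.names = list(names) if names else [f"s{d}" for d in range(self.dims)]
        for b in self.basins:
            if len(b.center) != self.dims or len(b.width) != self.dims:
                raise ValueError("basin center/width rank mismatch")
            if b.amplitude is None:
                b.amplitude = b.depth

    # -- evaluation ---------------------------------------------------------

    def energy(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        U = np.zeros(pts.shape[0])
        for b in self.basins:
            U += b.amplitude * b.factor(pts)
        return U

    def gradient(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        G = np.zeros_like(pts)
        for b in self.basins:
            f = b.amplitude * b.factor(pts)
            for d, (c, w) in enumerate(zip(b.center, b.width)):
                if c is None or w is None:
                    continue
                G[:, d] += f * (-(pts[:, d] - c) / (w * w))
        return G

    def __call__(self, pts) -> np.ndarray:
        return self.energy(pts)

    # -- helpers ------------------------------------------------------------

    def grid(self, spacing: Sequence[float]):
        """Regular evaluation grid: returns (axes, mesh points (n, dims))."""
        axes = [np.arange(lo, hi + 0.5 * ds, ds)
                for (lo, hi), ds in zip(self.domain, spacing)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        return axes, pts

    def basin_minimum(self, basin: Basin, spacing=None) -> float:
        """Grid-search minimum of U over the basin's neighbourhood (1.5 widths,
        inactive dims restricted to where every *other* basin is negligible)."""
        spacing = spacing or [0.1 if (hi - lo) < 100 else 0.5
                              for lo, hi in self.domain]
        axes = []
        for d, ((lo, hi), ds) in enumerate(zip(self.domain, spacing)):
            c, w = basin.center[d], basin.width[d]
            if c is not None and w is not None:
                axes.append(np.arange(max(lo, c - 1.5 * w),
                                      min(hi, c + 1.5 * w) + 0.5 * ds, ds))
            else:
                ax = np.arange(lo, hi + 0.5 * ds, ds)
                axes.append(ax)
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        # keep inactive-dim scan away from the other basins
        keep = np.ones(pts.shape[0], dtype=bool)
        if any(c is None for c in basin.center):
            for other in self.basins:
                if other is basin:
                    continue
                keep &= other.factor(pts) < 0.01
        if not keep.any():
            keep[:] = True
        return float(self.energy(pts[keep]).min())


def build_landscape(basins: Sequence[Basin], domain: Sequence[tuple],
                    names: Sequence[str] | None = None,
                    calibrate: bool = True,
                    tol: float = 0.1, max_iter: int = 60) -> AnalyticLandscape:
    """Build a landscape whose realised basin minima equal the configured
    depths to within ``tol`` kJ/mol.

    Overlapping wells perturb each other's minima, so amplitudes are solved by
    a fixed-point iteration on grid-searched minima. Landscapes whose depths
    cannot be realised (e.g. a shallow well swallowed by a deep overlapping
    one) are rejected.
    """
    for b in basins:
        if b.depth >= 0:
            raise ValueError("basin depths must be negative")
        if any(w is not None and w <= 0 for w in b.width):
            raise ValueError("basin widths must be positive")
    land = AnalyticLandscape(basins, domain, names)
    if not basins or not calibrate:
        return land
    for _ in range(max_iter):
        worst = 0.0
        for b in land.basins:
            m = land.basin_minimum(b)
            err = b.depth - m
            worst = max(worst, abs(err))
            b.amplitude += err
        if worst < 0.5 * tol:
            break
    else:
        raise ValueError("configured basin depths unreachable "
                         "(overlapping basins do not calibrate)")
    for b in land.basins:
        if b.amplitude >= 0:
            raise ValueError("configured basin depths unreachable "
                             "(calibration drove an amplitude positive)")
    return land


# -- the default study landscape -------------------------------------------

def two_basin_landscape(prone_depth: float = -11.5,
                        supine_depth: float = -11.9,
                        barrier: float = 6.5,
                        prone_center=(-6.0, 160.0),
                        supine_center=(2.0, 20.0),
                        prone_width=(2.0, 15.0),
                        supine_width=(2.0, 25.0),
                        trough_z: float = -2.0,
                        trough_width_z: float = 3.0,
                        domain=((-10.0, 42.0), (0.0, 180.0)),
                        tol: float = 0.1) -> AnalyticLandscape:
    """Two orientation basins joined by a membrane-associated trough.

    The trough depth is calibrated so that the rocking barrier — the lowest
    phi-crossing between the two basin minima at fixed z, measured from the
    shallower basin — equals ``barrier`` (kJ/mol). Defaults place the Prone
    basin at (z=-6 A, phi=160 deg) with depth -11.5 kJ/mol, the Supine basin
    at (z=+2 A, phi=20 deg) with depth -11.9 kJ/mol, and a 6.5 kJ/mol saddle.
    """
    shallow = max(prone_depth, supine_depth)
    trough_depth = shallow + barrier
    if trough_depth >= 0:
        raise ValueError("barrier exceeds the shallower basin depth; "
                         "the trough would not bind")
    basins = [
        Basin(center=prone_center, depth=prone_depth, width=prone_width),
        Basin(center=supine_center, depth=supine_depth, width=supine_width),
        Basin(center=(trough_z, None), depth=trough_depth,
              width=(trough_width_z, None)),
    ]
    land = build_landscape(basins, domain, names=("z", "phi"), tol=tol)

    # joint refinement: well depths and the realised saddle interact weakly,
    # so alternate point-fixes until both sit within tolerance
    from .thermo import landscape_barrier  # deferred import, no cycle at runtime
    wells, trough = land.basins[:2], land.basins[2]
    for _ in range(40):
        worst = 0.0
        for b in wells:
            err = b.depth - land.basin_minimum(b)
            b.amplitude += err
            worst = max(worst, abs(err))
        err = barrier - landscape_barrier(land, prone_center, supine_center)
        trough.amplitude += err  # shallower trough -> higher saddle -> larger barrier
        worst = max(worst, abs(err))
        if worst < 0.5 * tol:
            break
    return land


class CallableLandscape:
    """Adapter exposing arbitrary energy/gradient callables with the same
    interface as :class:`AnalyticLandscape` (used e.g. for harmonic tests)."""

    def __init__(self, energy_fn, grad_fn, domain, names=None):
        self._e, self._g = energy_fn, grad_fn
        self.domain = [tuple(map(float, d)) for d in domain]
        self.dims = len(self.domain)
        self.names = list(names) if names else [f"s{d}" for d in range(self.dims)]

    def energy(self, pts):
        return np.asarray(self._e(np.atleast_2d(np.asarray(pts, dtype=float))))

    def gradient(self, pts):
        return np.asarray(self._g(np.atleast_2d(np.asarray(pts, dtype=float))))

    def __call__(self, pts):
        return self.energy(pts)


def harmonic_1d(k: float = 1.0, center: float = 0.0,
                domain=((-20.0, 20.0),)) -> CallableLandscape:
    """U = k/2 (s - center)^2 on dimension 0; handy equipartition benchmark."""
    return CallableLandscape(
        lambda p: 0.5 * k * (p[:, 0] - center) ** 2,
        lambda p: np.stack([k * (p[:, 0] - center)], axis=-1),
        domain, names=("z",))


def double_well_1d(depth_a: float = -8.0, depth_b: float = -10.0,
                   center_a: float = 5.0, center_b: float = 15.0,
                   width: float = 1.5,
                   domain=((0.0, 30.0),)) -> AnalyticLandscape:
    """Small 1D double well used by the estimator and exchange tests."""
    basins = [
        Basin(center=(center_a,), depth=depth_a, width=(width,)),
        Basin(center=(center_b,), depth=depth_b, width=(width,)),
    ]
    return build_landscape(basins, domain, names=("z",))
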