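"""Windowed, bias-exchanged well-tempered metadynamics on analytic landscapes.

The sampling scheme mirrors the study design it emulates: the distance range
is divided into 4 Angstrom windows overlapping by 1 Angstrom, each flanked by
half-harmonic restraints; within every window three replicas run well-tempered
metadynamics, each biasing one of |z|, theta, phi; neighbouring replicas
attempt Metropolis configuration swaps in alternating even/odd pairings.
Dynamics are overdamped Langevin on the analytic landscape — a deliberately
minimal stand-in for the MD engine, sufficient to exercise every statistical
property of the estimator stack downstream.

State coordinates are always (z, theta, phi): z in Angstrom along the
landscape's first dimension, angles in degrees on [0, 180] with reflecting
boundaries. Energies kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .constants import KT_310

CV_NAMES = ("z", "theta", "phi")


# -- window scheme ----------------------------------------------------------

@dataclass(frozen=True)
class WindowScheme:
    """Ordered overlapping z-intervals with a common flank force constant."""

    windows: tuple          # of (lo, hi), Angstrom
    k: float                # kJ/mol/A^2

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def z_range(self) -> tuple:
        return self.windows[0][0], self.windows[-1][1]


def build_window_scheme(z_min: float, z_max: float, width: float = 4.0,
                        overlap: float = 1.0, k: float = 10.0) -> WindowScheme:
    """Tile [z_min, z_max] with ``width``-wide windows overlapping ``overlap``."""
    if overlap >= width:
        raise ValueError("overlap must be smaller than the window width")
    if z_max - z_min < width:
        raise ValueError("range narrower than one window")
    stride = width - overlap
    windows = []
    lo = z_min
    while True:
        windows.append((lo, lo + width))
        if lo + width >= z_max - 1e-9:
            break
        lo += stride
    return WindowScheme(windows=tuple(windows), k=float(k))


@dataclass(frozen=True)
class ReplicaSpec:
    """Replica index -> (window, biased CV) mapping: i // 3 is the window,
    i % 3 selects |z| (0), theta (1) or phi (2)."""

    index: int

    @property
    def window(self) -> int:
        return self.index // 3

    @property
    def cv_index(self) -> int:
        return self.index % 3

    @property
    def cv_name(self) -> str:
        return CV_NAMES[self.cv_index]


def build_replica_layout(scheme: WindowScheme) -> List[ReplicaSpec]:
    if scheme.n_windows < 1:
        raise ValueError("scheme must have at least one window")
    return [ReplicaSpec(i) for i in range(3 * scheme.n_windows)]


# -- well-tempered hills ----------------------------------------------------

def hill_height(v_local: float, w0: float, gamma: float,
                kT: float = KT_310) -> float:
    """Well-tempered deposition rule: w = w0 exp(-V/(kB dT)), kB dT = (gamma-1) kT."""
    if gamma <= 1.0:
        raise ValueError("bias factor gamma must exceed 1")
    return w0 * np.exp(-np.asarray(v_local) / ((gamma - 1.0) * kT))


@dataclass
class BiasState:
    """Deposited hills of one replica (all hills share one width here)."""

    sigma: float
    w0: float
    gamma: float
    stride: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_hills(self) -> int:
        return len(self.times)


def bias_energy(s, bias: BiasState, t: float = np.inf) -> np.ndarray:
    """Sum of Gaussian hills deposited strictly before time ``t``, at s."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if bias.n_hills == 0:
        return np.zeros_like(s)
    live = bias.times < t
    c, h = bias.centers[live], bias.heights[live]
    return (h * np.exp(-(s[:, None] - c) ** 2
                       / (2.0 * bias.sigma ** 2))).sum(axis=1)


def restraint_energy(z, window: tuple, k: float) -> np.ndarray:
    """Half-harmonic flanks: zero inside [lo, hi], k/2 (z-edge)^2 outside."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    lo, hi = window
    out = np.zeros_like(z)
    below = z < lo
    above = z > hi
    out[below] = 0.5 * k * (z[below] - lo) ** 2
    out[above] = 0.5 * k * (z[above] - hi) ** 2
    return out


def _restraint_force(z: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                     k: float) -> np.ndarray:
    f = np.zeros_like(z)
    below = z < lo
    above = z > hi
    f[below] = -k * (z[below] - lo[below])
    f[above] = -k * (z[above] - hi[above])
    return f


# -- Langevin parameters ----------------------------------------------------

@dataclass
class LangevinParams:
    """Overdamped Langevin parameters.

    ``mobility`` is dt/friction per coordinate (A^2 or deg^2 per (kJ/mol) per
    step): the update is s <- s - grad E * mobility + sqrt(2 kT mobility) xi.
    """

    kT: float = KT_310
    mobility: tuple = (0.05, 2.0, 2.0)
    n_steps: int = 100_000
    seed: int = 0
    hill_w0: float = 1.0
    hill_sigma: tuple = (1.0, 5.0, 5.0)   # per biased CV: A, deg, deg
    hill_stride: int = 500
    gamma: float = 10.0
    frame_stride: int = 20

    def __post_init__(self):
        if self.kT < 0 or any(m <= 0 for m in self.mobility):
            raise ValueError("kT must be >= 0 and mobilities > 0")


# -- campaign result containers --------------------------------------------

@dataclass
class ReplicaTrajectory:
    spec: ReplicaSpec
    window: tuple
    times: np.ndarray          # step index of each frame
    states: np.ndarray         # (n_frames, 3): z, theta, phi
    bias_at_frame: np.ndarray  # V_r(s_r, t) at each frame, kJ/mol
    bias: BiasState

    @property
    def biased_cv(self) -> np.ndarray:
        return self.states[:, self.spec.cv_index]


@dataclass
class CampaignResult:
    scheme: WindowScheme
    layout: List[ReplicaSpec]
    params: LangevinParams
    replicas: List[ReplicaTrajectory]
    exchange_attempts: int
    exchange_accepts: int

    @property
    def acceptance_rate(self) -> float:
        if self.exchange_attempts == 0:
            return 0.0
        return self.exchange_accepts / self.exchange_attempts


# -- exchange ---------------------------------------------------------------

def exchange_log_prob(state_i, state_j, bias_i, bias_j, window_i, window_j,
                      spec_i: ReplicaSpec, spec_j: ReplicaSpec, k: float,
                      kT: float, t: float = np.inf) -> float:
    """Log Metropolis acceptance probability for swapping two configurations
    between replicas carrying different biases and window restraints."""
    def total(bias, spec, window, state):
        v = float(bias_energy(state[spec.cv_index], bias, t)[0])
        r = float(restraint_energy(state[0], window, k)[0])
        return v + r
    delta = (total(bias_i, spec_i, window_i, state_j)
             + total(bias_j, spec_j, window_j, state_i)
             - total(bias_i, spec_i, window_i, state_i)
             - total(bias_j, spec_j, window_j, state_j))
    if kT == 0:
        return 0.0 if delta <= 0 else -np.inf
    return min(0.0, -delta / kT)


def attempt_exchange(rep_i: ReplicaSpec, rep_j: ReplicaSpec,
                     state_i, state_j, bias_i: BiasState, bias_j: BiasState,
                     window_i, window_j, k: float, rng,
                     kT: float = KT_310) -> bool:
    """Metropolis swap attempt between two *adjacent* replicas."""
    if abs(rep_i.index - rep_j.index) != 1:
        raise ValueError("exchange is only defined between adjacent replicas")
    logp = exchange_log_prob(np.atleast_1d(state_i), np.atleast_1d(state_j),
                             bias_i, bias_j, window_i, window_j,
                             rep_i, rep_j, k, kT)
    return np.log(rng.random()) < logp if logp < 0 else True


# -- the campaign -----------------------------------------------------------

class _BiasGrids:
    """Tabulated per-replica bias potentials for O(1) force evaluation."""

    def __init__(self, layout, scheme, z_domain, params):
        self.n = len(layout)
        g0, g1, dg = [], [], []
        for spec in layout:
            if spec.cv_index == 0:
                lo, hi = z_domain
                g0.append(lo - 2.0); g1.append(hi + 2.0); dg.append(0.2)
            else:
                g0.append(0.0); g1.append(180.0); dg.append(0.5)
        self.g0 = np.array(g0)
        self.dg = np.array(dg)
        self.npts = (np.ceil((np.array(g1) - self.g0) / self.dg) + 1).astype(int)
        m = self.npts.max()
        self.V = np.zeros((self.n, m))
        self.dV = np.zeros((self.n, m))
        self.grids = [self.g0[r] + self.dg[r] * np.arange(self.npts[r])
                      for r in range(self.n)]
        self.sigma = np.array([params.hill_sigma[s.cv_index] for s in layout])

    def _locate(self, s: np.ndarray):
        x = (s - self.g0) / self.dg
        x = np.clip(x, 0.0, self.npts - 1.001)
        i0 = x.astype(int)
        return i0, x - i0

    def value(self, s: np.ndarray) -> np.ndarray:
        i0, f = self._locate(s)
        rows = np.arange(self.n)
        return self.V[rows, i0] * (1 - f) + self.V[rows, i0 + 1] * f

    def grad(self, s: np.ndarray) -> np.ndarray:
        i0, f = self._locate(s)
        rows = np.arange(self.n)
        return self.dV[rows, i0] * (1 - f) + self.dV[rows, i0 + 1] * f

    def deposit(self, r: int, center: float, height: float) -> None:
        g = self.grids[r]
        sig = self.sigma[r]
        gauss = height * np.exp(-(g - center) ** 2 / (2 * sig * sig))
        self.V[r, :len(g)] += gauss
        self.dV[r, :len(g)] += gauss * (-(g - center) / (sig * sig))


def run_campaign(landscape, scheme: WindowScheme,
                 layout: Sequence[ReplicaSpec] | None = None,
                 params: LangevinParams = None,
                 exchange_stride: int = 250,
                 phi_start=None) -> CampaignResult:
    """Run all replicas of the windowed bias-exchange WT-MTD campaign.

    ``landscape`` supplies U and its gradient over (z,), (z, phi) or
    (z, theta, phi); coordinates the landscape omits evolve as free diffusion
    within their reflecting domains. All three replicas of a window feel that
    window's z-restraint. Deterministic given ``params.seed``.
    """
    params = params or LangevinParams()
    layout = list(layout) if layout is not None else build_replica_layout(scheme)
    rng = np.random.default_rng(params.seed)
    R = len(layout)
    dims = landscape.dims
    land_cols = {1: [0], 2: [0, 2], 3: [0, 1, 2]}[dims]
    z_dom = landscape.domain[0]
    dom_lo = np.array([z_dom[0], 0.0, 0.0])
    dom_hi = np.array([z_dom[1], 180.0, 180.0])

    wlo = np.array([scheme.windows[s.window][0] for s in layout])
    whi = np.array([scheme.windows[s.window][1] for s in layout])
    cv_idx = np.array([s.cv_index for s in layout])
    rows = np.arange(R)

    X = np.empty((R, 3))
    X[:, 0] = np.clip(0.5 * (wlo + whi), dom_lo[0], dom_hi[0])
    X[:, 1] = 90.0
    X[:, 2] = (rng.uniform(10.0, 170.0, size=R)
               if phi_start is None else float(phi_start))

    grids = _BiasGrids(layout, scheme, z_dom, params)
    hills = [BiasState(sigma=float(grids.sigma[r]), w0=params.hill_w0,
                       gamma=params.gamma, stride=params.hill_stride)
             for r in range(R)]
    hill_rec: List[list] = [[] for _ in range(R)]

    mob = np.asarray(params.mobility)
    noise_amp = np.sqrt(2.0 * params.kT * mob)
    kres = scheme.k
    gamma_kt = (params.gamma - 1.0) * params.kT if params.kT > 0 else np.inf

    frames_t: List[int] = []
    frames_x: List[np.ndarray] = []
    frames_v: List[np.ndarray] = []
    n_att = n_acc = 0
    span = dom_hi - dom_lo

    for step in range(params.n_steps + 1):
        s_biased = X[rows, cv_idx]

        if step % params.frame_stride == 0:
            frames_t.append(step)
            frames_x.append(X.copy())
            frames_v.append(grids.value(s_biased))

        if step == params.n_steps:
            break

        # forces
        F = np.zeros((R, 3))
        F[:, land_cols] = -landscape.gradient(X[:, land_cols])
        F[:, 0] += _restraint_force(X[:, 0], wlo, whi, kres)
        F[rows, cv_idx] += -grids.grad(s_biased)

        dX = F * mob + noise_amp * rng.standard_normal((R, 3))
        if np.abs(dX).max() > span.max():
            raise RuntimeError(
                f"divergent Langevin step at step {step}: |dX| max "
                f"{np.abs(dX).max():.3g} exceeds the domain span")
        X = X + dX
        # reflecting boundaries
        X = np.where(X < dom_lo, 2 * dom_lo - X, X)
        X = np.where(X > dom_hi, 2 * dom_hi - X, X)
        X = np.clip(X, dom_lo, dom_hi)

        if params.hill_w0 > 0 and (step + 1) % params.hill_stride == 0:
            s_now = X[rows, cv_idx]
            v_loc = grids.value(s_now)
            h = params.hill_w0 * np.exp(-v_loc / gamma_kt)
            for r in range(R):
                grids.deposit(r, s_now[r], h[r])
                hill_rec[r].append((step + 1, s_now[r], h[r]))

        if exchange_stride and (step + 1) % exchange_stride == 0:
            parity = ((step + 1) // exchange_stride) % 2
            for i in range(parity, R - 1, 2):
                j = i + 1

                def biased_energy(a: int, state: np.ndarray) -> float:
                    v = grids.value(np.full(R, state[cv_idx[a]]))[a]
                    rr = restraint_energy(state[0], (wlo[a], whi[a]), kres)[0]
                    return float(v + rr)

                de = (biased_energy(i, X[j]) + biased_energy(j, X[i])
                      - biased_energy(i, X[i]) - biased_energy(j, X[j]))
                n_att += 1
                if de <= 0 or (params.kT > 0
                               and rng.random() < np.exp(-de / params.kT)):
                    X[[i, j]] = X[[j, i]]
                    n_acc += 1

    replicas = []
    ft = np.array(frames_t, dtype=float)
    fx = np.array(frames_x)          # (n_f, R, 3)
    fv = np.array(frames_v)          # (n_f, R)
    for r in range(R):
        rec = np.array(hill_rec[r]).reshape(-1, 3)
        hills[r].times = rec[:, 0]
        hills[r].centers = rec[:, 1]
        hills[r].heights = rec[:, 2]
        replicas.append(ReplicaTrajectory(
            spec=layout[r], window=scheme.windows[layout[r].window],
            times=ft.copy(), states=fx[:, r, :], bias_at_frame=fv[:, r],
            bias=hills[r]))
    return CampaignResult(scheme=scheme, layout=layout, params=params,
                          replicas=replicas, exchange_attempts=n_att,
                          exchange_accepts=n_acc)


def langevin_run(landscape, params: LangevinParams, bias_cv: int = 0,
                 window: tuple = None, k: float = 0.0,
                 metadynamics: bool = True) -> ReplicaTrajectory:
    """Single-replica convenience wrapper around :func:`run_campaign`:
    one window (the whole z-domain unless given), one biased CV, optional
    metadynamics. Returns the replica trajectory with its hill record."""
    z_dom = landscape.domain[0]
    win = tuple(window) if window is not None else tuple(z_dom)
    scheme = WindowScheme(windows=(win,), k=float(k))
    layout = [ReplicaSpec(bias_cv)]
    if not metadynamics:
        from dataclasses import replace
        params = replace(params, hill_w0=0.0)
    out = run_campaign(landscape, scheme, layout, params, exchange_stride=0)
    return out.replicas[0]
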