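"""PMF reconstruction from windowed, bias-exchanged WT-MTD data.

The estimator is a composition of two published ideas:

1. *Time-independent metadynamics reweighting.* A well-tempered bias V(s, t)
   admits a time-dependent offset c(t) such that the frame weight
   exp(beta [V(s_i, t_i) - c(t_i)]) removes the metadynamics bias without
   waiting for V to converge;
   c(t) = kT ln [ int ds e^{beta gamma V/(gamma-1)} / int ds e^{beta V/(gamma-1)} ],
   a monotone non-decreasing series updated at every hill deposition.
2. *Binless WHAM across windows.* After metadynamics reweighting each replica
   behaves as a sample of its window-restraint ensemble; the per-window free
   energy shifts f_w are solved self-consistently without binning the bias:
   1/W_i = sum_w N_w exp(beta f_w - beta u_w(z_i)),
   exp(-beta f_w) = sum_i W_i exp(-beta u_w(z_i)).

The combined global weights feed histogram-based PMFs on 1D/2D grids, with
the zero of free energy set in a bulk reference slab and pointwise errors
from contiguous time blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KT_310
from .engine import (BiasState, CampaignResult, ReplicaTrajectory,
                     WindowScheme, bias_energy, restraint_energy)

AXIS_COLUMN = {"z": 0, "minzr": 0, "min_zr": 0, "theta": 1, "phi": 2}
DEFAULT_BIN = {"z": 1.0, "minzr": 1.0, "min_zr": 1.0, "theta": 5.0, "phi": 5.0}


@dataclass
class EstimatorConfig:
    wham_tol: float = 1e-10        # kJ/mol, max |delta f_w| at convergence
    max_iter: int = 500
    bin_width: dict = field(default_factory=lambda: dict(DEFAULT_BIN))
    bulk_slab: tuple | None = None  # (z_lo, z_hi); default: top 10 A sampled
    n_blocks: int = 5
    kT: float = KT_310

    def __post_init__(self):
        if self.wham_tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_blocks < 2:
            raise ValueError("block count must be >= 2")


@dataclass
class WeightedSamples:
    """Frames pooled across replicas with global (unnormalised) log-weights."""

    cvs: np.ndarray        # (n, 3): z, theta, phi
    times: np.ndarray
    replica: np.ndarray
    log_weight: np.ndarray
    f_windows: np.ndarray | None = None   # converged per-window shifts, kJ/mol

    def __post_init__(self):
        if not np.all(np.isfinite(self.log_weight)):
            raise ValueError("log-weights must be finite")

    @property
    def z(self) -> np.ndarray:
        return self.cvs[:, 0]

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class PMFGrid:
    """Binned free energy with axis metadata. Empty bins are NaN, never 0."""

    axes: List[tuple]        # (name, edges)
    F: np.ndarray            # kJ/mol
    error: np.ndarray | None = None
    reference: str = "bulk-slab-mean"

    def centers(self, i: int) -> np.ndarray:
        e = self.axes[i][1]
        return 0.5 * (e[:-1] + e[1:])

    @property
    def names(self) -> List[str]:
        return [a[0] for a in self.axes]


# -- metadynamics reweighting ----------------------------------------------

def metad_time_offset(bias: BiasState, kT: float = KT_310,
                      grid: np.ndarray = None):
    """c(t) series of the time-independent well-tempered estimator.

    Returns (times, c): one entry per hill deposition, evaluated on ``grid``
    (the biased CV's domain). Empty hill lists give an empty series, i.e.
    c identically zero.
    """
    if bias.n_hills == 0:
        return np.empty(0), np.empty(0)
    if grid is None:
        lo = bias.centers.min() - 5 * bias.sigma
        hi = bias.centers.max() + 5 * bias.sigma
        grid = np.linspace(lo, hi, 400)
    g = bias.gamma
    beta = 1.0 / kT
    V = np.zeros_like(grid)
    c = np.empty(bias.n_hills)
    for k in range(bias.n_hills):
        V += bias.heights[k] * np.exp(
            -(grid - bias.centers[k]) ** 2 / (2 * bias.sigma ** 2))
        num = logsumexp(beta * g / (g - 1.0) * V)
        den = logsumexp(beta / (g - 1.0) * V)
        c[k] = kT * (num - den)
    return bias.times.copy(), c


def metad_log_weights(traj: ReplicaTrajectory, kT: float = KT_310,
                      grid: np.ndarray = None) -> np.ndarray:
    """Per-frame log-weights beta (V(s_i, t_i) - c(t_i)) for one replica."""
    if grid is None:
        if traj.spec.cv_index == 0:
            lo, hi = traj.window
            grid = np.arange(lo - 2.0, hi + 2.0 + 1e-9, 0.1)
        else:
            grid = np.arange(0.0, 180.0 + 1e-9, 0.5)
    t_c, c = metad_time_offset(traj.bias, kT, grid)
    if len(t_c) == 0:
        return np.zeros(len(traj.times))
    idx = np.searchsorted(t_c, traj.times, side="right") - 1
    c_at = np.where(idx >= 0, c[np.clip(idx, 0, len(c) - 1)], 0.0)
    return (traj.bias_at_frame - c_at) / kT


# -- binless WHAM -----------------------------------------------------------

def wham_combine(replicas: Sequence[ReplicaTrajectory], scheme: WindowScheme,
                 cfg: EstimatorConfig = None,
                 equilibration: float = 0.0,
                 bias_offsets: Sequence[float] | None = None) -> WeightedSamples:
    """Merge metadynamics-reweighted replicas across windows.

    Each replica's metadynamics log-weights are normalised to its frame
    count; the per-window shifts f_w are then iterated to self-consistency
    over the half-harmonic restraint biases. Adjacent windows must share
    samples in their overlap, otherwise the estimator is disconnected and the
    gap is reported.

    ``equilibration`` drops that leading fraction of each replica's frames.
    ``bias_offsets`` adds a constant (kJ/mol) to each window's bias — a pure
    gauge: the final weights and any referenced PMF are unchanged.
    """
    cfg = cfg or EstimatorConfig()
    kT = cfg.kT
    cv_list, t_list, rep_list, a_list = [], [], [], []
    win_of_frame = []
    for traj in replicas:
        n0 = int(equilibration * len(traj.times))
        sl = slice(n0, None)
        lw = metad_log_weights(traj, kT)[sl]
        lw = lw - (logsumexp(lw) - np.log(len(lw)))
        cv_list.append(traj.states[sl])
        t_list.append(traj.times[sl])
        rep_list.append(np.full(len(lw), traj.spec.index))
        a_list.append(lw)
        win_of_frame.append(np.full(len(lw), traj.spec.window))
    cvs = np.concatenate(cv_list)
    times = np.concatenate(t_list)
    reps = np.concatenate(rep_list)
    ln_a = np.concatenate(a_list)
    wof = np.concatenate(win_of_frame)

    W = scheme.n_windows
    z = cvs[:, 0]
    for w in range(W - 1):
        lo_next = scheme.windows[w + 1][0]
        hi_this = scheme.windows[w][1]
        here = ((wof == w) | (wof == w + 1)) & (z >= lo_next) & (z <= hi_this)
        if not here.any():
            raise ValueError(
                f"windows {w} and {w + 1} share no samples in their overlap "
                f"[{lo_next}, {hi_this}] A — cannot stitch across the gap")

    beta = 1.0 / kT
    B = np.stack([beta * restraint_energy(z, win, scheme.k)
                  for win in scheme.windows], axis=1)       # (n, W)
    if bias_offsets is not None:
        B = B + beta * np.asarray(bias_offsets, dtype=float)[None, :]
    ln_N = np.array([logsumexp(ln_a[wof == w]) if (wof == w).any() else -np.inf
                     for w in range(W)])
    a = np.exp(ln_a)
    A = a.sum()
    abar = a / A
    Nbar = np.exp(ln_N) / A

    # The self-consistent equations are the stationarity condition of a
    # convex objective in the shifts g = beta f. A few fixed-point sweeps
    # give a stable start, then Newton iterations on the exact (W x W)
    # Hessian converge quadratically to the requested tolerance.
    g = np.zeros(W)
    for _ in range(5):
        D = logsumexp(ln_N[None, :] + g[None, :] - B, axis=1)
        g = -logsumexp((ln_a - D)[:, None] - B, axis=0)
        g -= g[0]
    converged = False
    for _ in range(cfg.max_iter):
        M = ln_N[None, :] + g[None, :] - B
        lse = logsumexp(M, axis=1)
        p = np.exp(M - lse[:, None])
        grad = abar @ p - Nbar
        # the objective is flat along weakly-determined directions; once the
        # gradient reaches machine noise the shifts are converged in every
        # direction the data constrain
        if np.abs(grad).max() < 1e-13:
            converged = True
            break
        pw = p * abar[:, None]
        H = np.diag(pw.sum(axis=0)) - p.T @ pw
        step = -np.linalg.lstsq(H, grad, rcond=1e-10)[0]
        nrm = np.abs(step).max()
        if nrm > 5.0:                      # damp far from the solution
            step *= 5.0 / nrm
        g = g + step
        g -= g[0]
        if nrm * kT < cfg.wham_tol:
            converged = True
            break
    if not converged:
        warnings.warn("WHAM did not reach tolerance; using last iterate")
    D = logsumexp(ln_N[None, :] + g[None, :] - B, axis=1)
    return WeightedSamples(cvs=cvs, times=times, replica=reps,
                           log_weight=ln_a - D, f_windows=g * kT)


# -- PMF grids --------------------------------------------------------------

def _resolve_axes(axes, cfg: EstimatorConfig, cvs: np.ndarray):
    """axes: sequence of names or (name, edges) -> [(name, edges), column]."""
    out, cols = [], []
    for ax in axes:
        if isinstance(ax, str):
            name, edges = ax, None
        else:
            name, edges = ax
        col = AXIS_COLUMN[name.lower()]
        if edges is None:
            w = cfg.bin_width.get(name.lower(), 1.0)
            lo = np.floor(cvs[:, col].min() / w) * w
            hi = np.ceil(cvs[:, col].max() / w) * w
            edges = np.arange(lo, hi + 0.5 * w, w)
        out.append((name, np.asarray(edges, dtype=float)))
        cols.append(col)
    return out, cols


def _reference_shift(F: np.ndarray, axes, cols, slab) -> float:
    """Mean F over non-empty bins whose z-center lies in the bulk slab."""
    if 0 not in cols:
        finite = F[np.isfinite(F)]
        if finite.size == 0:
            raise ValueError("PMF is empty; cannot reference")
        return float(finite.min())
    zi = cols.index(0)
    name, edges = axes[zi]
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_slab = (centers >= slab[0]) & (centers <= slab[1])
    if not in_slab.any():
        raise ValueError(f"bulk reference slab {slab} contains no bins")
    sel = np.moveaxis(F, zi, 0)[in_slab]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError(f"bulk reference slab {slab} has no sampled bins")
    return float(sel.mean())


def pmf_from_weights(samples: WeightedSamples, axes,
                     cfg: EstimatorConfig = None,
                     with_errors: bool = False) -> PMFGrid:
    """Weighted-histogram PMF on the requested axes.

    F = -kT ln(sum of weights per bin) + const, the constant chosen so the
    mean F over the bulk reference slab (top 10 A of the sampled z-range by
    default) is zero. Empty bins are NaN.
    """
    cfg = cfg or EstimatorConfig()
    ax_spec, cols = _resolve_axes(axes, cfg, samples.cvs)
    slab = cfg.bulk_slab
    if slab is None and 0 in cols:
        z_hi = samples.z.max()
        slab = (z_hi - 10.0, z_hi)
    lw = samples.log_weight - samples.log_weight.max()
    hist, _ = np.histogramdd(samples.cvs[:, cols],
                             bins=[a[1] for a in ax_spec],
                             weights=np.exp(lw))
    with np.errstate(divide="ignore"):
        F = np.where(hist > 0, -cfg.kT * np.log(np.where(hist > 0, hist, 1.0)),
                     np.nan)
    F -= _reference_shift(F, ax_spec, cols, slab)
    err = None
    if with_errors:
        err = block_errors(samples, cfg.n_blocks, axes, cfg)
    return PMFGrid(axes=ax_spec, F=F, error=err)


def block_errors(samples: WeightedSamples, n_blocks: int, axes,
                 cfg: EstimatorConfig = None) -> np.ndarray:
    """Pointwise standard error of F over contiguous time blocks.

    Each block is re-referenced to the bulk slab before the spread is taken;
    blocks whose reference slab is unsampled are dropped with a warning.
    """
    cfg = cfg or EstimatorConfig()
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    ax_spec, cols = _resolve_axes(axes, cfg, samples.cvs)
    slab = cfg.bulk_slab
    if slab is None and 0 in cols:
        z_hi = samples.z.max()
        slab = (z_hi - 10.0, z_hi)
    t_edges = np.linspace(samples.times.min(), samples.times.max() + 1e-9,
                          n_blocks + 1)
    lw = samples.log_weight - samples.log_weight.max()
    w_all = np.exp(lw)
    blocks = []
    for b in range(n_blocks):
        m = (samples.times >= t_edges[b]) & (samples.times < t_edges[b + 1])
        if not m.any():
            continue
        hist, _ = np.histogramdd(samples.cvs[m][:, cols],
                                 bins=[a[1] for a in ax_spec],
                                 weights=w_all[m])
        with np.errstate(divide="ignore"):
            Fb = np.where(hist > 0,
                          -cfg.kT * np.log(np.where(hist > 0, hist, 1.0)),
                          np.nan)
        try:
            Fb -= _reference_shift(Fb, ax_spec, cols, slab)
        except ValueError:
            warnings.warn(f"block {b} has an empty reference slab; excluded")
            continue
        blocks.append(Fb)
    if len(blocks) < 2:
        raise ValueError("fewer than two usable blocks for error estimation")
    stack = np.stack(blocks)
    n_def = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1)
    err = sd / np.sqrt(np.maximum(n_def, 1))
    err[n_def < 2] = np.nan
    return err


def reconstruct_pmf(campaign: CampaignResult, axes,
                    cfg: EstimatorConfig = None,
                    equilibration: float = 0.1,
                    with_errors: bool = True) -> PMFGrid:
    """End-to-end: metadynamics reweighting + WHAM + binned, referenced PMF."""
    cfg = cfg or EstimatorConfig()
    samples = wham_combine(campaign.replicas, campaign.scheme, cfg,
                           equilibration=equilibration)
    return pmf_from_weights(samples, axes, cfg, with_errors=with_errors)


# -- analytic oracle --------------------------------------------------------

def landscape_reference_pmf(landscape, axes, cfg: EstimatorConfig = None,
                            subdiv: int = 5) -> PMFGrid:
    """Direct Boltzmann integral of an analytic landscape on a PMF grid:
    F_bin = -kT ln int_bin e^{-beta U}, referenced like the estimator output.
    Serves as the independent ground truth for recovery tests."""
    cfg = cfg or EstimatorConfig()
    names = [(a if isinstance(a, str) else a[0]) for a in axes]
    cols = [AXIS_COLUMN[n.lower()] for n in names]
    land_cols = {1: [0], 2: [0, 2], 3: [0, 1, 2]}[landscape.dims]
    edges = []
    for a, col in zip(axes, cols):
        if not isinstance(a, str):
            edges.append(np.asarray(a[1], dtype=float))
        else:
            w = cfg.bin_width.get(a.lower(), 1.0)
            if col == 0:
                lo, hi = landscape.domain[0]
            else:
                lo, hi = 0.0, 180.0
            edges.append(np.arange(lo, hi + 0.5 * w, w))
    fine_axes = []
    for e in edges:
        centers = []
        for i in range(len(e) - 1):
            centers.append(np.linspace(e[i], e[i + 1], subdiv + 2)[1:-1])
        fine_axes.append(np.concatenate(centers))
    # landscape dimensions the requested grid omits are marginalised by
    # integrating over their full domain
    hidden = [c for c in land_cols if c not in cols]
    for c in hidden:
        lo, hi = landscape.domain[land_cols.index(c)]
        w_hidden = 5.0 if c > 0 else 1.0
        he = np.arange(lo, hi + 0.5 * w_hidden, w_hidden)
        centers = [np.linspace(he[i], he[i + 1], subdiv + 2)[1:-1]
                   for i in range(len(he) - 1)]
        fine_axes.append(np.concatenate(centers))
    all_cols = cols + hidden
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    pts = np.zeros((mesh[0].size, 3))
    for m, col in zip(mesh, all_cols):
        pts[:, col] = m.ravel()
    U = landscape.energy(pts[:, land_cols])
    w = np.exp(-U / cfg.kT).reshape(mesh[0].shape)
    if hidden:
        w = w.sum(axis=tuple(range(len(cols), len(all_cols))))
    shape = tuple(len(e) - 1 for e in edges)
    w = w.reshape(tuple(x for n in shape for x in (n, subdiv))) \
        .sum(axis=tuple(range(1, 2 * len(shape), 2)))
    F = -cfg.kT * np.log(w)
    slab = cfg.bulk_slab
    if slab is None and 0 in cols:
        z_hi = edges[cols.index(0)][-1]
        slab = (z_hi - 10.0, z_hi)
    ax_spec = list(zip(names, edges))
    F -= _reference_shift(F, ax_spec, cols, slab)
    return PMFGrid(axes=ax_spec, F=F, reference="bulk-slab-mean (analytic)")
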