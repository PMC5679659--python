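# Methods

## Scope and model

`memfes` re-implements, as a tested library, the analysis machinery of an
orientation-resolved protein–membrane binding study: collective-variable
geometry, windowed bias-exchange well-tempered metadynamics (WT-MTD), PMF
reconstruction by combined metadynamics reweighting and binless WHAM,
per-orientation binding thermodynamics, and per-residue lipid statistics.
Atomistic MD itself is out of scope: the sampler runs overdamped Langevin
dynamics on analytic free-energy landscapes, which stand in for the real
system while preserving every statistical property the estimators rely on.

Units throughout: lengths nm internally (Å at the CV and window interfaces,
matching how such quantities are reported), energies kJ/mol, angles degrees,
charges e. kT = 2.577 kJ/mol at 310 K.

## Collective variables

The protein carries two orientation axes defined by fixed residue groups
(each axis is the unit vector between the Cα centroids of its "pink" and
"blue" groups, oriented pink→blue). Relative to the membrane normal — the
unit vector between the P-atom centroids of the two leaflets — the CVs are
|z| (projected Cα-COM to upper-P-COM distance, Å), θ (long axis), φ (short
axis), and min z_r (lowest Cα z relative to the upper-leaflet P plane, Å).
θ and φ are reported on [0°, 180°] as angles of the *oriented* axes: an
unsigned-line convention would fold the two binding orientations together.

Mode classification: Prone iff φ > 140° and min z_r < +10 Å; Supine iff
φ < 40° and membrane-associated; Unbound iff min z_r > +20 Å; otherwise
Intermediate. The angle cutoffs follow the observed orientation basins; the
z cutoffs are package conventions and config-exposed, since no numeric
association cutoff is canonical. The classification is total by
construction.

## Synthetic landscapes

The default ground truth is a two-basin surface over (z, φ):

- Prone basin at (−6 Å, 160°), depth −11.5 kJ/mol, widths (2 Å, 15°);
- Supine basin at (+2 Å, 20°), depth −11.9 kJ/mol, widths (2 Å, 25°)
  (wider in φ — the surface-adsorbed state is the more plastic one);
- a membrane-associated trough in z only, joining the basins along φ so the
  protein can rock between orientations without detaching.

Basin depths and the rocking saddle are *calibrated*, not nominal: Gaussian
amplitudes are fixed-point-iterated until each realised grid minimum matches
its configured depth within 0.1 kJ/mol and the realised saddle (lowest
φ-crossing between the basin minima at fixed z, measured from the shallower
basin) equals the configured 6.5 kJ/mol. Landscapes whose configured depths
cannot be realised (e.g. a shallow well inside a deep one) are rejected.
U → 0 in the bulk region by construction, which anchors the free-energy
reference.

## Sampling scheme

The z-range [−10, 42] Å is tiled with 4 Å windows overlapping 1 Å (17
windows), each flanked by half-harmonic restraints (default
k = 10 kJ/mol/Å², config-exposed). Every window runs three WT-MTD replicas
biasing z, θ and φ respectively (replica i: window i div 3, CV i mod 3); all
three share the window's z-restraint. Hills: initial height w0 = 1 kJ/mol,
widths 1 Å / 5°, stride 500 steps, bias factor γ = 10; heights decay as
w0·exp(−V/( (γ−1)kT )). These hill parameters are package defaults chosen to
flatten ~12 kJ/mol basins comfortably; all are config-exposed.

Dynamics: overdamped Euler–Maruyama, s ← s − ∇E·a + √(2 kT a)·ξ with
per-coordinate mobility a = dt/friction (defaults 0.05 Å²/(kJ/mol)/step in
z, 2.0 deg²/(kJ/mol)/step in angles). The scheme has the usual O(a)
discretisation bias (e.g. the stationary variance of a harmonic well is
kT/k·1/(1−ka/2)); tests that check equilibrium statistics use a small enough
mobility that this bias sits well inside their tolerance. Angles use
reflecting boundaries at 0° and 180°, matching the arccos range of the real
CVs; z reflects at the landscape domain edges. A step larger than the domain
span aborts with a diagnostic.

Bias exchange: every 250 steps, configuration swaps are attempted between
adjacent replica indices in alternating even/odd pairings, accepted with the
Metropolis probability built from both replicas' metadynamics biases and
window restraints evaluated at both configurations. With identical biases
the move is always accepted; tests verify that exchange leaves the per-replica
stationary distributions unchanged (χ² on/off comparison).

## PMF reconstruction

Two estimators are composed, in this order:

1. **Time-independent WT-MTD reweighting.** Each replica's frames get
   log-weights β[V(s_i, t_i) − c(t_i)], with
   c(t) = kT ln[∫ds e^{βγV/(γ−1)} / ∫ds e^{βV/(γ−1)}] evaluated on the
   biased CV's domain at every hill deposition (c is monotone
   non-decreasing; no hills ⇒ c ≡ 0 and uniform weights; a static bias
   reduces the weights to standard umbrella reweighting). After this step
   each replica is, in expectation, a weighted sample of its
   window-restraint ensemble.
2. **Binless WHAM across windows.** With per-replica weights normalised to
   frame counts, the per-window shifts f_w solve
   exp(−βf_w) = Σ_i W_i e^{−βu_w(z_i)},
   W_i = a_i / Σ_w N_w e^{βf_w − βu_w(z_i)}.
   These are the stationarity conditions of a convex objective in βf; the
   solver runs five fixed-point sweeps for a stable start and then Newton
   iterations with the exact W×W Hessian, converging to the requested
   tolerance (default 10⁻¹⁰ kJ/mol) in a handful of passes. Directions the
   data barely constrain make the Hessian near-singular; once the gradient
   reaches machine noise the solution is accepted, since the objective is
   flat there. Adding a constant to any window's bias is a pure gauge
   (shifts f_w, leaves all weights and referenced PMFs unchanged);
   adjacent windows with no shared samples in their 1 Å overlap are a hard
   error naming the gap.

The reconstruction is approximate in one acknowledged respect: after a bias
exchange, a replica's history mixes configurations generated under its own
and its neighbours' biases, while reweighting uses each replica's own bias
history. The recovery tests bound the practical impact: a full 17-window
campaign at 10⁵ steps per replica reconstructs the planted surface within
1 kJ/mol RMS over all bins below 10 kJ/mol.

PMFs are weighted histograms, F = −kT ln Σw + const, on 1 Å × 5° bins by
default (contour-level resolution; finer bins add noise, not information).
The constant zeroes the mean F over a bulk reference slab — by default the
top 10 Å of the sampled z-range, where the landscape has decayed. Empty bins
are NaN, never zero. Pointwise errors are standard errors over contiguous
time blocks (default 5), each block re-referenced to the bulk slab; blocks
with an unsampled slab are dropped with a warning.

## Binding thermodynamics

Per-mode association free energy:
ΔG = −kT ln[ W_mode / (ρ_bulk · Δφ_mode · w_slab) ], where W_mode is the
Boltzmann weight of the mode rectangle (φ-band × z-band), ρ_bulk the bulk
weight density per (Å·deg), and w_slab a reference z-slab width (default
1 Å). This makes ΔG a per-orientation association free energy under an
explicit, config-exposed volume convention; the exact convention is a
choice, so every numerical claim about ΔG in the tests is either
convention-internal (shift and monotonicity properties) or compares the
estimator against the direct Boltzmann integral of the landscape under the
same convention. Errors propagate weight-averaged block errors from the PMF
grid.

The rocking barrier is the minimum over z-rows (within the
membrane-associated band) of the maximum F along φ between the two basin
minima, measured from the shallower basin — i.e. the lowest reorientation
path that never detaches. Straight φ-paths per row suffice because the
mechanism is a rotation about the long axis at roughly constant insertion;
no 2D minimum-energy-path search is attempted. A missing basin makes the
barrier undefined (an error, not a number).

The thermodynamic cycle is the pointwise difference of the cholesterol-bound
and apo 1D PMFs over min z_r on a common grid with a common bulk reference:
ΔΔG(min z_r) = ΔG^chol-bound(min z_r) − ΔG^apo(min z_r). Identical inputs
give exactly zero; a uniform shift of one input appears with opposite sign;
grid mismatches are rejected rather than interpolated.

## Interaction statistics

**NCF.** Residue r contacts species s in a frame iff the minimum atom
distance is ≤ 0.4 nm (config-exposed; per-frame binary counting).
NCF(r) = counts(r, BMP)/Σ_s counts(r, s), undefined (NaN, flagged) where a
residue saw no lipid; residues above 0.4 are flagged for display. The
planted-contact generator places each probed residue on a grid 3 cutoffs
apart with a dedicated bead per (residue, species), drawing the contacting
species categorically per frame — so the planted probabilities are the exact
expectation of the empirical frequencies, and recovery is a binomial-error
statement, not a modelling claim.

**SASA.** Shrake–Rupley with per-atom radii: points on each subset atom's
expanded sphere (r + probe) are accessible iff outside every other atom's
expanded sphere; all atoms occlude, and for slab geometries the eight
in-plane periodic images occlude too. The quadrature point set (golden
spiral, default 960 points) is randomly rotated per atom with a fixed seed:
with a shared orientation the per-atom quantisation error is coherent across
a lattice and can bias summed areas of tiny exposed caps by tens of percent;
rotation decoheres it, making summed areas unbiased while keeping results
deterministic. An isolated sphere reproduces 4π(r+R)² within 2%; a random
cluster cross-checks against an independent implementation (biotite).

The dual-probe ratio uses 0.14 nm (water) and 0.58 nm — the minimal
bounding-sphere radius R_min = 0.066·M^(1/3) nm of the 694 Da insertion
loop. The printed-source form of that relation carries a garbled exponent;
the cube-root form is used because it alone reproduces the stated 0.58 nm
(0.066·√694 would give 1.74 nm). The ratio is raw (no per-probe
normalisation): it lies in [0, 1] for slab-like geometries, which is the
intended regime, but not for isolated convex bodies, where it exceeds 1.
Groove test geometries are sealed underneath with full base layers, because
Shrake–Rupley accessibility is a purely local test and an open underside
would count as exposed surface.

**Electrostatics.** Charge density binned along z (optionally after
centring the lipid COM at the box midplane), integrated to the field with a
midpoint rule — E at bin centers, which keeps the discrete field exactly
antisymmetric for mirror-symmetric densities — then to ψ = −∫E dz with
ψ(0) = 0. Mirror-averaging over the two box halves (appropriate for
bilayers with statistically equivalent leaflets, and the default) also pins
ψ to zero at both edges; it must be disabled for intrinsically asymmetric
charge layouts, which it would erase. Non-neutral frames are flagged: their
field cannot close. Profiles are frame-averaged with standard-error bands;
potentials are kJ/mol/e internally, volts on output.

## Synthetic generators: what they do and do not emulate

The generators reproduce the *statistical and geometric structure* the
estimators consume — basin topology and depths, window/replica layout,
composition fractions (largest-remainder rounding, counts exact), leaflet
tagging, contact probabilities, probe-exclusion geometry — with seeded,
bit-reproducible determinism. They deliberately do not emulate lipid
conformational detail, solvent, protein flexibility, or force-field physics.
Consequently, passing tests demonstrate the correctness of the estimator
machinery on systems with known answers; they do not validate any claim
about real membranes, where sampling is harder and the CVs are noisier.

## Problem sizes

The default full-campaign verification runs 17 windows × 3 replicas at 10⁵
Langevin steps each (frames every 20 steps, hills every 500), reconstructing
on a 52 × 36 grid — about 20 s for sampling and 6 s for reconstruction on a
single core. Estimator identity tests use one- and two-window campaigns at
2–6 × 10⁴ steps. These sizes were chosen as the smallest at which the
recovery tolerances are comfortably resolved by the statistics.

## Known limitations

- The exchange/reweighting approximation described above; exact treatment
  would require demultiplexing continuous trajectories through bias space.
- WHAM assumes uncorrelated samples when normalising per-replica weights to
  frame counts; autocorrelation inflates effective counts equally across
  windows, which cancels in f_w differences but not in the error model —
  block errors carry that burden instead.
- The barrier search is restricted to straight φ-paths per z-row.
- `sasa_ratio` is meaningful for slab-like subsets; isolated convex bodies
  fall outside its [0, 1] interpretation.
- The toy engine's angles are plain reflecting coordinates, not true
  spherical angles; the Jacobian sin θ weighting of real orientation space
  is not emulated.
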