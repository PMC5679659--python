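"""Run a windowed bias-exchange WT-MTD campaign on the built-in two-basin
landscape and reconstruct the 2D PMF.

The landscape plants a deep-inserted basin at (min z_r = -6 A, phi = 160 deg,
-11.5 kJ/mol), a surface-adsorbed basin at (+2 A, 20 deg, -11.9 kJ/mol) and a
6.5 kJ/mol rocking saddle between them. A full 17-window x 3-replica campaign
takes ~20 s; this example uses a shorter run for speed.
"""

import numpy as np

import memfes as m

land = m.two_basin_landscape()
scheme = m.build_window_scheme(-10.0, 42.0, width=4.0, overlap=1.0, k=10.0)
print(f"{scheme.n_windows} windows -> "
      f"{len(m.build_replica_layout(scheme))} replicas")

params = m.LangevinParams(n_steps=40_000, seed=5, frame_stride=20)
camp = m.run_campaign(land, scheme, params=params, exchange_stride=250)
print(f"exchange acceptance rate: {camp.acceptance_rate:.2f}")

pmf = m.reconstruct_pmf(camp, ["z", "phi"], equilibration=0.1)
ref = m.landscape_reference_pmf(land, [("z", pmf.axes[0][1]),
                                       ("phi", pmf.axes[1][1])])
mask = np.isfinite(pmf.F) & np.isfinite(ref.F) & (ref.F < 10)
rms = np.sqrt(np.mean((pmf.F[mask] - ref.F[mask]) ** 2))
print(f"PMF recovery RMS vs analytic ground truth (F < 10 kJ/mol): "
      f"{rms:.2f} kJ/mol")

barrier = m.interconversion_barrier(pmf)
print(f"recovered rocking barrier along phi: {barrier:.1f} kJ/mol "
      f"(configured 6.5) — the protein can reorient without detaching")
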