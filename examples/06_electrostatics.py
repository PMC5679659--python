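"""Electrostatic potential profile of a toy anionic membrane.

The charge density along the membrane normal is integrated twice:
rho -> field -> potential, mirror-averaged over the two box halves and
pinned to zero at the box edges.
"""

import numpy as np

import memfes as m

membrane = m.build_membrane_patch([20, 10, 0, 0, 70], n_lipids=400, seed=4)
# neutralise with counter-ion charges spread at the box edges
n_bmp = m.species_counts(membrane)["BMP"]
rng = np.random.default_rng(4)
# the membrane sits at z ~ 0; put the counter-ions in the water slabs
# +-4.5 nm away so everything stays inside the box after centring
ion_xyz = np.stack([rng.uniform(0, membrane.box[0], n_bmp),
                    rng.uniform(0, membrane.box[1], n_bmp),
                    rng.choice([-4.5, 4.5], n_bmp)], axis=-1)
ions = m.ToyStructure(
    names=np.full(n_bmp, "NA"), resids=np.arange(1, n_bmp + 1) + 10000,
    resnames=np.full(n_bmp, "ION"), species=np.full(n_bmp, "ION"),
    xyz=ion_xyz, charges=np.ones(n_bmp), radii=np.full(n_bmp, 0.12),
    box=membrane.box.copy())
system = m.concat(membrane, ions)
print(f"total charge: {system.charges.sum():+.0f} e")

profile = m.electrostatic_profile([system], n_bins=120)
i_min = np.argmin(profile.potential)
print(f"potential minimum: {profile.potential_volts[i_min] * 1000:.0f} mV "
      f"at z = {profile.z_centers[i_min]:.1f} nm (membrane interior)")
print(f"edge values: {profile.potential[0]:.2e} / "
      f"{profile.potential[-1]:.2e} kJ/mol/e (zero by construction)")
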