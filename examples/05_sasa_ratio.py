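"""Dual-probe SASA ratio: how accessible is a surface to the insertion loop?

The ratio compares the summed SASA at a loop-sized probe (0.58 nm, from
R_min = 0.066 M^(1/3) at M = 694 Da) to a water-sized probe (0.14 nm): ~1
means the loop reaches the surface as freely as water, ~0 means the surface
is only presented through crevices narrower than the loop.
"""

import memfes as m
from memfes.constants import MIL_SEQUENCE

mass = m.residue_set_mass(MIL_SEQUENCE)
print(f"insertion loop {MIL_SEQUENCE}: mass {mass:.0f} Da -> probe radius "
      f"{m.probe_radius_from_mass(mass):.2f} nm")

flat = m.build_groove_surface(0.0, atom_radius=0.14, extent=(3.0, 1.5))
mean, sd = m.sasa_ratio([flat], subset_of=lambda s: s.names == "FL",
                        n_points=960)
print(f"flat surface: sasa-ratio = {mean:.2f} +- {sd:.2f} "
      f"(equal accessibility)")

groove = m.build_groove_surface(0.40, depth=0.5, atom_radius=0.14,
                                extent=(3.0, 1.5))
mean, sd = m.sasa_ratio([groove], subset_of=lambda s: s.names == "FL",
                        n_points=960)
print(f"0.40 nm groove floor: sasa-ratio = {mean:.2f} +- {sd:.2f} "
      f"(water enters, the loop cannot)")
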