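"""Build the toy protein and an anionic membrane patch, then classify a pose.

The membrane mixture BMP:CHOL:SM:DOPG:POPC = 20:10:0:0:70 is the anionic,
BMP-rich composition at which the protein binds strongly in two orientations.
"""

import memfes as m

protein = m.build_toy_protein(seed=1)
membrane = m.build_membrane_patch([20, 10, 0, 0, 70], n_lipids=200, seed=2)
print("membrane species counts:", m.species_counts(membrane))

ref = m.membrane_normal(membrane)
print(f"membrane normal = {ref.normal.round(3)}, "
      f"upper P plane at z = {ref.upper_p_z:.2f} nm")

# Pose the protein in the deep-inserted orientation (pocket facing the
# membrane, short axis 160 deg from the normal, lowest Calpha 6 A below the
# phosphate plane) and read the collective variables back.
posed = m.pose_protein(protein, phi_deg=160.0, min_zr=-6.0,
                       upper_p_z=ref.upper_p_z)
cv = m.compute_cvs(m.concat(posed, membrane), ref)
print(f"CVs: |z| = {cv.z_abs:.1f} A, theta = {cv.theta:.0f} deg, "
      f"phi = {cv.phi:.0f} deg, min z_r = {cv.min_zr:.1f} A")
print("classified mode:", m.classify_mode(cv).value)
print(f"pocket-opening residue depth: "
      f"{m.g61_insertion_depth(m.concat(posed, membrane), ref):.1f} A "
      f"(negative = inserted)")
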