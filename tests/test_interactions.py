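"""Contacts/NCF, dual-probe SASA, electrostatic profiles."""

import numpy as np
import pytest

import memfes as m
from memfes.constants import EPS0
from memfes.interactions import ContactCounts, SASAConfig, sasa
from conftest import point_structure


class TestContacts:
    def _frame(self, lipid_offset_nm):
        import memfes.structures as st
        prot = point_structure([[0.0, 0.0, 0.0]], species="PROT")
        prot.names[:] = "CA"
        lip = point_structure([[lipid_offset_nm, 0.0, 0.0]], species="BMP")
        return st.concat(prot, lip)

    def test_contact_within_cutoff_counts_once(self):
        counts = m.residue_lipid_contacts(self._frame(0.3), cutoff=0.4)
        assert counts.counts == {(1, "BMP"): 1}

    def test_no_contacts_beyond_cutoff(self):
        counts = m.residue_lipid_contacts(self._frame(1.2), cutoff=0.4)
        assert counts.counts == {}

    def test_planted_probabilities_recovered_within_binomial_error(self):
        spec = {7: {"BMP": 0.5, "POPC": 0.5}}
        traj = m.emit_planted_trajectory(spec, 1500, seed=3)
        counts = m.accumulate_contacts(
            (traj.structure_at(i) for i in range(traj.n_frames)), traj.cutoff)
        for sp, p in spec[7].items():
            freq = counts.counts[(7, sp)] / traj.n_frames
            assert freq == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 1500))


class TestNCF:
    def test_ratio_arithmetic(self):
        c = ContactCounts(counts={(1, "BMP"): 8, (1, "POPC"): 2,
                                  (2, "BMP"): 0, (2, "POPC"): 5})
        prof = m.ncf_profile(c)
        assert prof.ncf[prof.residues == 1][0] == pytest.approx(0.8)
        assert prof.ncf[prof.residues == 2][0] == 0.0

    def test_scale_free(self):
        base = {(1, "BMP"): 3, (1, "SM"): 1, (2, "BMP"): 2, (2, "POPC"): 2}
        p1 = m.ncf_profile(ContactCounts(counts=dict(base)))
        p2 = m.ncf_profile(ContactCounts(
            counts={k: 17 * v for k, v in base.items()}))
        assert np.allclose(p1.ncf, p2.ncf)

    def test_specific_residue_peaks_in_profile(self):
        spec = {r: {"BMP": 0.2, "POPC": 0.8} for r in range(55, 70)}
        spec[61] = {"BMP": 1.0}
        traj = m.emit_planted_trajectory(spec, 400, seed=8)
        counts = m.accumulate_contacts(
            (traj.structure_at(i) for i in range(traj.n_frames)), traj.cutoff)
        prof = m.ncf_profile(counts)
        assert prof.residues[np.nanargmax(prof.ncf)] == 61
        assert prof.flagged().tolist() == [61]

    def test_mean_and_sd_across_systems(self):
        p1 = m.ncf_profile(ContactCounts(counts={(1, "BMP"): 1,
                                                 (1, "POPC"): 1}))
        p2 = m.ncf_profile(ContactCounts(counts={(1, "BMP"): 1}))
        residues, mean, sd = m.ncf_across_systems([p1, p2])
        assert mean[0] == pytest.approx(0.75)
        assert sd[0] == pytest.approx(0.25)


class TestProbeSizing:
    def test_insertion_loop_probe_radius(self):
        assert round(m.probe_radius_from_mass(694.0), 2) == 0.58

    @pytest.mark.parametrize("mass,expected", [(0.0, 0.0), (1000.0, 0.66)])
    def test_mass_scaling(self, mass, expected):
        assert m.probe_radius_from_mass(mass) == pytest.approx(expected)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            m.probe_radius_from_mass(-1.0)

    def test_insertion_loop_sequence_mass(self):
        assert m.residue_set_mass("VMGIPVP") == pytest.approx(694.0, abs=0.5)

    def test_empty_and_glycine_masses(self):
        assert m.residue_set_mass("") == 0.0
        assert m.residue_set_mass("GG") == pytest.approx(114.1, abs=0.1)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            m.residue_set_mass("VMX")


class TestSASA:
    def test_isolated_sphere_matches_closed_form(self):
        s = point_structure([[0.0, 0.0, 0.0]], radii=[0.2])
        for probe in (0.14, 0.58):
            a = sasa(s, SASAConfig(probe, 960))[0]
            exact = 4 * np.pi * (0.2 + probe) ** 2
            assert abs(a - exact) / exact < 0.02

    def test_enclosed_atom_has_zero_area(self):
        from memfes.interactions import _sphere_points
        shell = 0.35 * _sphere_points(200)
        xyz = np.vstack([[0.0, 0.0, 0.0], shell])
        s = point_structure(xyz, radii=np.full(len(xyz), 0.2))
        assert sasa(s, SASAConfig(0.14, 480), np.array([0]))[0] == 0.0

    def test_occlusion_is_monotone(self):
        rng = np.random.default_rng(5)
        xyz = rng.uniform(0, 1.5, (12, 3))
        s_few = point_structure(xyz[:8], radii=np.full(8, 0.18))
        s_all = point_structure(xyz, radii=np.full(12, 0.18))
        cfg = SASAConfig(0.14, 480)
        a_few = sasa(s_few, cfg, np.arange(8))
        a_all = sasa(s_all, cfg, np.arange(8))
        assert np.all(a_all <= a_few + 1e-12)

    def test_cross_check_against_independent_implementation(self):
        """Random cluster vs biotite's Shrake-Rupley with the same radii."""
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(6)
        xyz = rng.uniform(0, 1.2, (20, 3))
        radii = rng.uniform(0.15, 0.25, 20)
        s = point_structure(xyz, radii=radii)
        ours = sasa(s, SASAConfig(0.14, 960, rotate_points=False))
        arr = biotite_struct.AtomArray(20)
        arr.coord = (xyz * 10).astype(np.float32)   # biotite works in Angstrom
        arr.set_annotation("element", np.full(20, "C", dtype="U2"))
        theirs = biotite_struct.sasa(arr, probe_radius=1.4,
                                     vdw_radii=(radii * 10).astype(float),
                                     point_number=960) / 100.0  # A^2 -> nm^2
        assert np.allclose(ours, theirs, rtol=0.06, atol=0.02)

    def test_missing_radius_rejected(self):
        s = point_structure([[0.0, 0.0, 0.0]], radii=[np.nan])
        with pytest.raises(ValueError):
            sasa(s, SASAConfig(0.14, 480))


class TestSASARatio:
    def test_identical_frames_have_zero_spread(self):
        g = m.build_groove_surface(0.0, atom_radius=0.14, extent=(1.5, 1.0))
        mean, sd = m.sasa_ratio([g, g],
                                subset_of=lambda s: s.names == "FL",
                                n_points=240)
        assert sd == 0.0

    def test_flat_surface_ratio_near_one(self):
        flat = m.build_groove_surface(0.0, atom_radius=0.14, extent=(3.0, 1.5))
        mean, _ = m.sasa_ratio([flat], subset_of=lambda s: s.names == "FL",
                               n_points=960)
        assert mean == pytest.approx(1.0, abs=0.15)

    def test_narrow_grooves_bury_subset_for_large_probe(self):
        g = m.build_groove_surface(0.40, depth=0.5, atom_radius=0.14,
                                   extent=(3.0, 1.5))
        mean, _ = m.sasa_ratio([g], subset_of=lambda s: s.names == "FL",
                               n_points=960)
        assert mean == pytest.approx(0.0, abs=1e-9)


class TestElectrostatics:
    def test_zero_charges_zero_potential(self):
        rng = np.random.default_rng(7)
        s = point_structure(rng.uniform(0, 5, (50, 3)), box=(5, 5, 5))
        prof = m.electrostatic_profile([s], 100, center_on_membrane=False)
        assert np.all(prof.potential == 0.0)

    @staticmethod
    def _sheet(z, q_per_atom, nx=30, box=4.0):
        g = np.linspace(box / nx / 2, box - box / nx / 2, nx)
        xs, ys = np.meshgrid(g, g)
        n = xs.size
        xyz = np.stack([xs.ravel(), ys.ravel(), np.full(n, z)], axis=-1)
        return xyz, np.full(n, q_per_atom)

    def test_parallel_plate_closed_form(self):
        xyz1, q1 = self._sheet(4.0, +0.01)
        xyz2, q2 = self._sheet(8.0, -0.01)
        s = point_structure(np.vstack([xyz1, xyz2]),
                            charges=np.concatenate([q1, q2]),
                            box=(4.0, 4.0, 12.0))
        prof = m.electrostatic_profile([s], 500, center_on_membrane=False,
                                       symmetrize=False)
        sigma = q1.sum() / 16.0
        expected = sigma * 4.0 / EPS0
        below = prof.potential[prof.z_centers < 3.8]
        above = prof.potential[prof.z_centers > 8.2]
        assert below.std() < 1e-9 and above.std() < 1e-6  # flat outside
        assert below.mean() - above.mean() == pytest.approx(expected,
                                                            rel=0.01)

    def test_mirror_symmetric_charges_give_symmetric_potential(self):
        # charges placed on bin centers of the 200-bin grid, mirror pairs
        xyz1, q1 = self._sheet(2.97, +0.01)
        xyz2, q2 = self._sheet(9.03, +0.01)
        xyz3, q3 = self._sheet(5.97, -0.01)
        xyz4, q4 = self._sheet(6.03, -0.01)
        s = point_structure(np.vstack([xyz1, xyz2, xyz3, xyz4]),
                            charges=np.concatenate([q1, q2, q3, q4]),
                            box=(4.0, 4.0, 12.0))
        prof = m.electrostatic_profile([s], 200, center_on_membrane=False)
        peak = np.abs(prof.potential).max()
        assert peak > 0
        assert np.abs(prof.potential - prof.potential[::-1]).max() < 1e-6 * peak
        assert abs(prof.potential[0]) < 1e-6 * peak
        assert abs(prof.potential[-1]) < 1e-6 * peak

    def test_non_neutral_frame_warns(self):
        s = point_structure([[1.0, 1.0, 1.0]], charges=[1.0], box=(4, 4, 4))
        with pytest.warns(UserWarning, match="neutral"):
            m.electrostatic_profile([s], 50, center_on_membrane=False)
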