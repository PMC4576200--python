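"""Determinism and ground-truth fidelity of the synthetic-data generators."""

import copy

import numpy as np
import pytest

from helixprobe import anomalous as an
from helixprobe import metal_geometry as mg
from helixprobe import structure_io as sio
from helixprobe import synthetic_data as sd
from tests.conftest import peakset_from_crystal


class TestDeterminism:
    def test_octahedral_site_byte_identical(self, tmp_path):
        paths = []
        for i in (1, 2):
            s = sd.make_octahedral_site(seed=11, distortion_sd=0.05)
            p = tmp_path / f"site{i}.pdb"
            sio.write_pdb(s, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_alignment_identical(self):
        a = sd.make_alignment_with_repeats(seed=5, mutation_rate=0.1)
        b = sd.make_alignment_with_repeats(seed=5, mutation_rate=0.1)
        assert a.records == b.records

    def test_equilibrium_profile_identical(self):
        a = sd.make_equilibrium_profile(mass=20000.0, noise_sd=0.01, seed=9)
        b = sd.make_equilibrium_profile(mass=20000.0, noise_sd=0.01, seed=9)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_toy_crystal_structure_factors_identical(self):
        kw = dict(wavelength=0.9, resolution=1.2, background_atoms=100, seed=3)
        atoms = [("S", (0.2, 0.3, 0.4), 1.0, 10.0)]
        a = sd.make_toy_anomalous_crystal((8.0, 8.0, 8.0), atoms, **kw)
        b = sd.make_toy_anomalous_crystal((8.0, 8.0, 8.0), atoms, **kw)
        assert np.array_equal(a.f_plus, b.f_plus)
        assert np.array_equal(a.bdf_map, b.bdf_map)


class TestOctahedralSiteGenerator:
    def test_zero_distortion_gives_perfect_fit(self):
        site = mg.find_metal_sites(sd.make_octahedral_site(seed=8))[0]
        fit = mg.octahedral_fit(site)
        assert fit.edge_rmsd == pytest.approx(0.0, abs=1e-9)
        assert fit.position_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_shell_mean_near_requested_radius(self):
        site = mg.find_metal_sites(
            sd.make_octahedral_site(radius=2.16, distortion_sd=0.05, seed=3)
        )[0]
        (mean, _), _ = mg.shell_statistics(site)
        assert abs(mean - 2.16) <= 0.05

    def test_calcium_radius_classifies_as_calcium(self):
        site = mg.find_metal_sites(
            sd.make_octahedral_site(metal="Ca", radius=2.46, seed=0)
        )[0]
        assert mg.classify_metal_by_distance(site.inner_mean)[0][0] == "Ca2+"

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="radius"):
            sd.make_octahedral_site(radius=-1.0)
        with pytest.raises(ValueError, match="distortion"):
            sd.make_octahedral_site(distortion_sd=-0.1)


class TestToyCrystal:
    def test_all_f_double_prime_zero_gives_flat_map(self):
        table = copy.deepcopy(an.DEFAULT_TABLE)
        for el in table.f_double_prime:
            table.f_double_prime[el][:] = 0.0
        tc = sd.make_toy_anomalous_crystal(
            (10.0, 10.0, 10.0),
            [("S", (0.2, 0.3, 0.4), 1.0, 10.0), ("Ca", (0.6, 0.5, 0.7), 1.0, 10.0)],
            wavelength=0.9, resolution=1.0, background_atoms=50, seed=1, table=table,
        )
        assert np.abs(tc.bdf_map).max() < 1e-8
        assert tc.peaks == []

    def test_ca_to_s_peak_ratio_tracks_f_double_prime(self, crystal_ca_s):
        heights = {p.label: p.height_sigma for p in crystal_ca_s.peaks}
        expected = an.expected_peak_ratio("Ca", "S", 0.9)
        assert heights["CA1"] / heights["S1"] == pytest.approx(expected, rel=0.10)

    def test_ratio_consistent_across_grid_sizes(self):
        """Direct-summation self-check: coarser FFT grid, same refined ratio."""
        atoms = [("S", (0.1, 0.2, 0.3), 1.0, 10.0), ("Ca", (0.6, 0.7, 0.2), 1.0, 10.0)]
        fine = sd.make_toy_anomalous_crystal(
            (12.0, 12.0, 12.0), atoms, 0.9, 1.0, background_atoms=1000, seed=2)
        coarse = sd.make_toy_anomalous_crystal(
            (12.0, 12.0, 12.0), atoms, 0.9, 1.3, background_atoms=1000, seed=2)
        rf = {p.label: p.height_sigma for p in fine.peaks}
        rc = {p.label: p.height_sigma for p in coarse.peaks}
        assert rf["CA1"] / rf["S1"] == pytest.approx(rc["CA1"] / rc["S1"], rel=0.15)

    def test_planted_partial_occupancy_recovered(self, crystal_sr_partial):
        ps = peakset_from_crystal(crystal_sr_partial, {"S1", "S2", "S3"})
        est = an.estimate_occupancy(ps, "SR1", "Sr")
        assert est.occupancy == pytest.approx(0.07, abs=0.02)

    def test_peak_heights_linear_in_occupancy(self):
        """Absolute BDF peak values scale linearly with planted occupancy."""
        occs = [0.05, 0.1, 0.25, 0.5, 1.0]
        values = []
        for occ in occs:
            tc = sd.make_toy_anomalous_crystal(
                (12.0, 12.0, 12.0),
                [("S", (0.1, 0.15, 0.2), 1.0, 10.0), ("Sr", (0.7, 0.6, 0.75), occ, 10.0)],
                wavelength=0.9, resolution=1.0, background_atoms=3000, seed=7,
            )
            h = {p.label: p.height_sigma * tc.map_sigma for p in tc.peaks}
            values.append(h["SR1"])
        r = np.corrcoef(occs, values)[0, 1]
        assert r * r > 0.98
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_size_guards(self):
        with pytest.raises(ValueError, match="0.8"):
            sd.make_toy_anomalous_crystal((8.0, 8.0, 8.0), [("S", (0, 0, 0), 1.0, 10.0)],
                                          resolution=0.5)
        too_many = [("S", (i / 60, 0.5, 0.5), 1.0, 10.0) for i in range(51)]
        with pytest.raises(ValueError, match="50 marker"):
            sd.make_toy_anomalous_crystal((8.0, 8.0, 8.0), too_many)
        with pytest.raises(ValueError, match="grid"):
            sd.make_toy_anomalous_crystal((60.0, 60.0, 60.0), [("S", (0, 0, 0), 1.0, 10.0)],
                                          resolution=1.0)

    def test_peak_positions_at_planted_sites(self, crystal_ca_s):
        cell = np.array(crystal_ca_s.cell)
        for peak in crystal_ca_s.peaks:
            if peak.atom_index >= 0 and peak.label in {"S1", "CA1"}:
                planted = np.array(crystal_ca_s.atoms[peak.atom_index][1])
                d = np.array(peak.frac_position) - planted
                d -= np.round(d)
                assert np.linalg.norm(d * cell) < 0.5


class TestAlignmentGenerator:
    def test_zero_mutation_recovers_planted_repeats_everywhere(self):
        aln = sd.make_alignment_with_repeats(
            n_sequences=8, length=96, copies=4, mutation_rate=0.0, seed=1
        )
        from helixprobe.seqrepeat import find_repeats

        offset = (96 - 32) // 2
        for _, seq in aln.records:
            hits = find_repeats(seq, "VxGxxxxx", 2)
            assert any(h.start == offset and h.copies >= 4 for h in hits)

    def test_planted_all_trp_column(self):
        aln = sd.make_alignment_with_repeats(n_sequences=6, seed=2, motif="WxGxxxxx")
        from helixprobe.seqrepeat import sidechain_size_profile

        offset = (120 - 32) // 2
        prof = sidechain_size_profile(aln)
        assert prof.mean_sidechain_atoms[offset] == 10.0  # W column conserved

    def test_region_must_fit(self):
        with pytest.raises(ValueError, match="exceeds"):
            sd.make_alignment_with_repeats(length=20, copies=4)


class TestTrimerToyGenerator:
    def test_three_identical_chains(self):
        t = sd.make_trimer_toy(6, "closed")
        assert t.chain_ids == ["A", "B", "C"]
        per_chain = [sum(1 for a in t.atoms if a.chain_id == c) for c in "ABC"]
        assert per_chain == [6, 6, 6]

    def test_packing_validation(self):
        with pytest.raises(ValueError, match="packing"):
            sd.make_trimer_toy(4, "dense")
        with pytest.raises(ValueError, match="at least 2"):
            sd.make_trimer_toy(1, "open")


class TestEquilibriumGenerator:
    def test_physical_parameter_validation(self):
        with pytest.raises(ValueError, match="positive"):
            sd.make_equilibrium_profile(mass=-1.0)
        with pytest.raises(ValueError, match="vbar"):
            sd.make_equilibrium_profile(mass=1e4, vbar=1.2, density=1.0)

    def test_hexamer_scale_profile(self):
        """A 14.1 kDa species reads as a trimer of 4.7 kDa chains."""
        from helixprobe.biophys import fit_equilibrium_mass, oligomer_state

        p = sd.make_equilibrium_profile(mass=14100.0)
        assert oligomer_state(fit_equilibrium_mass(p).mass, 4700.0) == 3
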