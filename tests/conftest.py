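"""Shared fixtures: hand-written coordinate fixtures and cached toy crystals."""

from __future__ import annotations

import textwrap

import pytest

from helixprobe import synthetic_data as sd

# Hand-written 3-atom fixture: one Mg ion and two water oxygens.
THREE_ATOM_PDB = textwrap.dedent(
    """\
    ATOM      1  CA  GLY A   1       0.000   0.000   5.000  1.00 10.00           C
    HETATM    2 MG    MG A  90       0.000   0.000   0.000  1.00 10.00          MG
    HETATM    3  O   HOH A  91       2.100   0.000   0.000  1.00 15.00           O
    HETATM    4  O   HOH A  92       0.000   2.200   0.000  1.00 15.00           O
    END
    """
)
# note: 4 atoms total; the "3-atom" Mg/O/O hetero subset plus one protein CA
# so selection tests can distinguish hetero from polymer records.


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three_atom.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def octahedral_site_structure():
    return sd.make_octahedral_site(metal="Mg", radius=2.16, seed=3)


@pytest.fixture(scope="session")
def crystal_ca_s():
    """Full-occupancy S + Ca in a light-atom bulk (for ratio checks)."""
    atoms = [("S", (0.1, 0.2, 0.3), 1.0, 10.0), ("Ca", (0.6, 0.7, 0.2), 1.0, 10.0)]
    return sd.make_toy_anomalous_crystal(
        (12.0, 12.0, 12.0), atoms, wavelength=0.9, resolution=1.0,
        background_atoms=3000, seed=2,
    )


@pytest.fixture(scope="session")
def crystal_sr_partial():
    """Three full-occupancy S references plus Sr planted at occupancy 0.07."""
    atoms = [
        ("S", (0.1, 0.15, 0.2), 1.0, 10.0),
        ("S", (0.7, 0.3, 0.6), 1.0, 10.0),
        ("S", (0.4, 0.8, 0.35), 1.0, 10.0),
        ("Sr", (0.75, 0.65, 0.85), 0.07, 10.0),
    ]
    return sd.make_toy_anomalous_crystal(
        (12.0, 12.0, 12.0), atoms, wavelength=0.9, resolution=1.0,
        background_atoms=3000, seed=4,
    )


def peakset_from_crystal(crystal, reference_labels):
    """Build an anomalous.PeakSet from a ToyCrystal peak list."""
    from helixprobe.anomalous import Peak, PeakSet

    return PeakSet(
        peaks=[Peak(p.label, p.height_sigma) for p in crystal.peaks],
        reference_labels=frozenset(reference_labels),
        wavelength=crystal.wavelength,
    )
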