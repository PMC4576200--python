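"""Seeded generators of synthetic inputs for every analysis stage.

Each generator emulates the statistical structure one pipeline stage assumes:

* ``make_octahedral_site``: a hydrated metal site — six water oxygens at
  perturbed octahedron vertices plus an optional outer shell — under a random
  rigid rotation.
* ``make_toy_anomalous_crystal``: a tiny P1 cell with known anomalous
  scatterers; structure factors from direct summation with complex scattering
  factors f0 + f' + i f'', a Bijvoet-difference Fourier map on a modest grid,
  and a peak list in map-sigma units.  Peak heights track occupancy x f'',
  which is the premise behind sulfur-calibrated occupancy estimation.
* ``make_alignment_with_repeats``: homolog-like alignments sharing a planted
  tandem motif region over i.i.d. uniform background.
* ``make_equilibrium_profile``: exponential sedimentation-equilibrium
  absorbance profiles with Gaussian noise.
* ``make_trimer_toy``: three sphere-chains with 3-fold symmetry whose closed
  packing fully buries designated axial spheres.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .anomalous import DEFAULT_TABLE, AnomalousTable
from .biophys import GAS_CONSTANT, EquilibriumProfile
from .seqrepeat import AMINO_ACIDS, Alignment
from .structure_io import AtomRecord, Structure

__all__ = [
    "make_octahedral_site",
    "make_toy_anomalous_crystal",
    "make_alignment_with_repeats",
    "make_equilibrium_profile",
    "make_trimer_toy",
    "ToyCrystal",
    "ToyPeak",
]

_OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_octahedral_site(
    metal: str = "Mg",
    radius: float = 2.16,
    distortion_sd: float = 0.0,
    outer_count: int = 3,
    outer_radius: float = 4.21,
    seed: int = 0,
) -> Structure:
    """A hydrated metal site: metal at the origin, waters on octahedron vertices.

    The six inner water oxygens sit at perturbed octahedron vertices
    (isotropic Gaussian displacement of sd *distortion_sd*); *outer_count*
    additional waters sit on a ring at *outer_radius* below the octahedron
    (the second hydration sphere).  A seeded random rigid rotation is applied
    to the whole site.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if distortion_sd < 0:
        raise ValueError("distortion_sd must be >= 0")
    rng = np.random.default_rng(seed)
    inner = _OCTAHEDRON * radius
    if distortion_sd > 0:
        inner = inner + rng.normal(scale=distortion_sd, size=inner.shape)
    outer = []
    if outer_count > 0:
        # ring below the octahedron, tilted 135 deg off +z like a second shell
        polar = math.radians(135.0)
        for k in range(outer_count):
            az = 2.0 * math.pi * k / outer_count
            outer.append(
                outer_radius
                * np.array(
                    [
                        math.sin(polar) * math.cos(az),
                        math.sin(polar) * math.sin(az),
                        math.cos(polar),
                    ]
                )
            )
    R = _random_rotation(rng)
    atoms = [
        AtomRecord(
            serial=1,
            name=metal.upper(),
            element=metal.capitalize(),
            residue_name=metal.upper(),
            residue_number=1,
            chain_id="A",
            position=(0.0, 0.0, 0.0),
            is_hetero=True,
        )
    ]
    for i, pos in enumerate(list(inner) + outer):
        rotated = R @ pos
        atoms.append(
            AtomRecord(
                serial=i + 2,
                name="O",
                element="O",
                residue_name="HOH",
                residue_number=i + 2,
                chain_id="A",
                position=tuple(float(x) for x in rotated),
                is_hetero=True,
            )
        )
    return Structure(atoms=atoms, source_id=f"synthetic-{metal}-site", title="synthetic hydrated metal site")


@dataclass(frozen=True)
class ToyPeak:
    label: str
    height_sigma: float
    frac_position: tuple[float, float, float]
    atom_index: int  # nearest generator atom, -1 if unmatched


@dataclass
class ToyCrystal:
    """Direct-summation toy crystal: structure factors, BDF map, peak list."""

    cell: tuple[float, float, float]
    atoms: list[tuple[str, tuple[float, float, float], float, float]]
    wavelength: float
    resolution: float
    hkl: np.ndarray  # unique half-set, shape (n, 3)
    f_plus: np.ndarray  # F(+h), complex
    f_minus: np.ndarray  # F(-h), complex
    bdf_map: np.ndarray  # real, shape (N, N, N)
    map_sigma: float
    peaks: list[ToyPeak] = field(default_factory=list)


def _it92_f0(element: str, stol2: np.ndarray) -> np.ndarray:
    """Thomson scattering factor from the standard 4-Gaussian approximation."""
    el = gemmi.Element(element)
    coef = el.it92
    if coef is None:
        raise KeyError(f"no IT92 coefficients for element {element!r}")
    stol2 = np.atleast_1d(stol2)
    a = np.array(coef.a)
    b = np.array(coef.b)
    return coef.c + (a[None, :] * np.exp(-b[None, :] * stol2[:, None])).sum(axis=1)


def make_toy_anomalous_crystal(
    cell: tuple[float, float, float],
    atoms: list[tuple[str, tuple[float, float, float], float, float]],
    wavelength: float = 0.9,
    resolution: float = 1.0,
    seed: int = 0,
    background_atoms: int = 0,
    b_factor_default: float = 10.0,
    grid_max: int = 64,
    table: AnomalousTable = DEFAULT_TABLE,
) -> ToyCrystal:
    """Simulate a P1 toy crystal and its Bijvoet-difference Fourier map.

    Parameters
    ----------
    cell:
        Orthorhombic cell lengths (a, b, c) in Å.
    atoms:
        ``(element, (x, y, z) fractional, occupancy, B)`` per atom.
    wavelength:
        X-ray wavelength in Å (sets f', f'').
    resolution:
        High-resolution cutoff in Å; must be >= 0.8 (size guard).
    seed:
        Seeds the placement of *background_atoms*.
    background_atoms:
        Number of full-occupancy carbon atoms scattered uniformly through
        the cell, emulating the protein bulk.  Bijvoet differences arise
        from interference between anomalous and normal scatterers, so a
        cell containing only the anomalous atoms gives a degenerate map.
        Moreover the standard synthesis carries a second-order "ghost"
        term that coherently suppresses peaks in proportion to the
        anomalous atoms' share of the total normal scattering: peak
        heights track occupancy x f'' only when that share is small, as
        it is in a real protein crystal (thousands of light atoms per
        site).  Use ~3000 background atoms for quantitative ratio tests;
        overlap between randomly placed atoms is irrelevant to the
        interference statistics.

    The BDF map uses coefficients (|F+| - |F-|) exp(i(phi - 90 deg)) with
    phi the phase of the non-anomalous (f0 + f') calculated structure
    factor — the standard anomalous-difference synthesis whose peak heights
    are proportional to occupancy x f'' at equal B.
    """
    if resolution < 0.8:
        raise ValueError("resolution finer than 0.8 Å exceeds the toy-scale guard")
    if len(atoms) > 50:
        raise ValueError("more than 50 marker atoms exceeds the toy-scale guard")
    if background_atoms > 4000:
        raise ValueError("more than 4000 background atoms exceeds the toy-scale guard")
    if len(atoms) + background_atoms == 0:
        raise ValueError("at least one atom is required")
    atoms = list(atoms)
    if background_atoms:
        rng = np.random.default_rng(seed)
        for _ in range(background_atoms):
            atoms.append(
                ("C", tuple(rng.uniform(size=3)), 1.0, b_factor_default)
            )
    a, b, c = cell
    hmax = int(a / resolution) + 1
    kmax = int(b / resolution) + 1
    lmax = int(c / resolution) + 1
    n_grid = 1
    while n_grid < 2 * max(hmax, kmax, lmax) + 1:
        n_grid *= 2
    if n_grid > grid_max:
        raise ValueError(
            f"cell/resolution would need a {n_grid}^3 grid (> {grid_max}^3); "
            "use a smaller cell or coarser resolution"
        )

    # unique half-set: l > 0, or (l == 0 and k > 0), or (l == k == 0 and h > 0)
    hh, kk, ll = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    half = (
        (hkl[:, 2] > 0)
        | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0))
    )
    hkl = hkl[half]
    inv_d2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    keep = inv_d2 <= 1.0 / resolution**2
    hkl = hkl[keep]
    stol2 = inv_d2[keep] / 4.0  # (sin theta / lambda)^2

    f_plus = np.zeros(len(hkl), dtype=complex)
    f_minus = np.zeros(len(hkl), dtype=complex)
    f_real = np.zeros(len(hkl), dtype=complex)  # non-anomalous model (f0 + f')
    by_element: dict[str, list[int]] = {}
    for i, (element, _, _, _) in enumerate(atoms):
        by_element.setdefault(element.capitalize(), []).append(i)
    for el, idx in by_element.items():
        f0 = _it92_f0(el, stol2)  # (n_refl,)
        fp = table._interp(table.f_prime, el, wavelength)
        fdp = table._interp(table.f_double_prime, el, wavelength)
        frac = np.array([atoms[i][1] for i in idx])  # (n_el, 3)
        occ = np.array([atoms[i][2] for i in idx])
        bfac = np.array(
            [atoms[i][3] if atoms[i][3] is not None else b_factor_default for i in idx]
        )
        contrib = np.zeros(len(hkl), dtype=complex)
        contrib_conj = np.zeros(len(hkl), dtype=complex)
        for lo in range(0, len(idx), 512):  # chunked to bound memory
            sl = slice(lo, lo + 512)
            phase = np.exp(2j * math.pi * (hkl @ frac[sl].T))  # (n_refl, chunk)
            dw = np.exp(-np.outer(stol2, bfac[sl]))
            contrib += (occ[None, sl] * dw * phase).sum(axis=1)
            contrib_conj += (occ[None, sl] * dw * np.conj(phase)).sum(axis=1)
        f_plus += (f0 + fp + 1j * fdp) * contrib
        f_minus += (f0 + fp + 1j * fdp) * contrib_conj
        f_real += (f0 + fp) * contrib

    # BDF synthesis on an n_grid^3 FFT grid
    delta = np.abs(f_plus) - np.abs(f_minus)
    phi = np.angle(f_real)
    coeff = delta * np.exp(1j * (phi - math.pi / 2.0))
    G = np.zeros((n_grid, n_grid, n_grid), dtype=complex)
    for (h, k, l), cval in zip(hkl, coeff):
        G[h % n_grid, k % n_grid, l % n_grid] += cval
        G[-h % n_grid, -k % n_grid, -l % n_grid] += np.conj(cval)
    # crystallographic convention rho(x) = sum_h F(h) exp(-2 pi i h.x)
    bdf = np.fft.fftn(G).real

    # map sigma over grid points farther than 2 Å from any atom center
    from scipy.spatial import cKDTree

    cellvec = np.array([a, b, c])
    idx = np.indices((n_grid, n_grid, n_grid)).reshape(3, -1).T / n_grid
    atom_xyz = (np.array([frac for _, frac, _, _ in atoms]) % 1.0) * cellvec
    tree = cKDTree(atom_xyz, boxsize=cellvec)
    nearest, _ = tree.query(idx * cellvec)
    mask = nearest < 2.0
    background = bdf.ravel()[~mask]
    sigma = float(background.std()) if background.size else float(bdf.std())
    if sigma == 0:
        sigma = 1e-12

    peaks = _find_peaks(bdf, sigma, atoms, cell, n_grid, hkl=hkl, coeff=coeff)
    return ToyCrystal(
        cell=cell,
        atoms=list(atoms),
        wavelength=wavelength,
        resolution=resolution,
        hkl=hkl,
        f_plus=f_plus,
        f_minus=f_minus,
        bdf_map=bdf,
        map_sigma=sigma,
        peaks=peaks,
    )


def _direct_map_value(hkl: np.ndarray, coeff: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Evaluate the difference synthesis directly at fractional positions."""
    phase = np.exp(-2j * math.pi * (np.atleast_2d(frac) @ hkl.T))
    return 2.0 * (phase @ coeff).real


def _refine_peak(
    hkl: np.ndarray, coeff: np.ndarray, frac0: np.ndarray, cell: np.ndarray, step_ang: float
) -> tuple[np.ndarray, float]:
    """Sub-grid peak refinement: local search of the direct synthesis."""
    best_frac, best_val = frac0, float(_direct_map_value(hkl, coeff, frac0)[0])
    span = step_ang / cell  # one grid step in fractional units per axis
    for _ in range(2):
        offsets = np.linspace(-0.6, 0.6, 5)
        grid = np.array(
            [
                best_frac + np.array([dx, dy, dz]) * span
                for dx in offsets
                for dy in offsets
                for dz in offsets
            ]
        )
        vals = _direct_map_value(hkl, coeff, grid)
        i = int(np.argmax(vals))
        best_frac, best_val = grid[i], float(vals[i])
        span = span / 2.0
    return best_frac, best_val


def _find_peaks(
    bdf: np.ndarray,
    sigma: float,
    atoms: list,
    cell: tuple[float, float, float],
    n_grid: int,
    hkl: np.ndarray,
    coeff: np.ndarray,
    threshold: float = 3.0,
) -> list[ToyPeak]:
    """Local maxima above *threshold* sigma, labeled by nearest atom (< 1.5 Å).

    Heights are refined off-grid by evaluating the difference synthesis
    directly around each grid maximum, so they do not depend on whether an
    atom happens to sit on a grid point.
    """
    from scipy.ndimage import maximum_filter

    local_max = bdf == maximum_filter(bdf, size=3, mode="wrap")
    above = bdf > threshold * sigma
    coords = np.argwhere(local_max & above)
    # refine only the strongest maxima; weaker ones are ripple/ghost noise
    order = np.argsort([-bdf[tuple(c)] for c in coords])
    coords = coords[order[:40]]
    cellvec = np.array(cell)
    element_counts: dict[str, int] = {}
    labels_by_atom: dict[int, str] = {}
    for i, (element, _, _, _) in enumerate(atoms):
        element_counts[element] = element_counts.get(element, 0) + 1
        labels_by_atom[i] = f"{element.upper()}{element_counts[element]}"
    step_ang = float(min(cellvec)) / n_grid
    afrac = np.array([a[1] for a in atoms])
    raw: list[tuple[np.ndarray, float, int]] = []
    for ijk in coords:
        frac, value = _refine_peak(hkl, coeff, ijk / n_grid, cellvec, step_ang)
        frac = frac % 1.0
        d = frac[None, :] - afrac
        d -= np.round(d)
        dist = np.linalg.norm(d * cellvec, axis=1)
        best_atom = int(np.argmin(dist))
        raw.append((frac, value, best_atom if dist[best_atom] < 1.5 else -1))
    # merge maxima that refined into the same peak: keep the highest per
    # atom, and the highest of unmatched maxima closer than one grid step
    raw.sort(key=lambda t: -t[1])
    peaks: list[ToyPeak] = []
    taken_atoms: set[int] = set()
    kept_frac: list[np.ndarray] = []
    n_unmatched = 0
    for frac, value, atom_idx in raw:
        if atom_idx >= 0:
            if atom_idx in taken_atoms:
                continue
            taken_atoms.add(atom_idx)
            label = labels_by_atom[atom_idx]
        else:
            d = [
                np.linalg.norm(((frac - f) - np.round(frac - f)) * cellvec)
                for f in kept_frac
            ]
            if d and min(d) < 2.0 * step_ang:
                continue
            n_unmatched += 1
            label = f"U{n_unmatched}"
        kept_frac.append(frac)
        peaks.append(
            ToyPeak(
                label=label,
                height_sigma=float(value / sigma),
                frac_position=tuple(float(x) for x in frac),
                atom_index=atom_idx,
            )
        )
    return peaks


def make_alignment_with_repeats(
    n_sequences: int = 20,
    length: int = 120,
    motif: str = "VxGxxxxx",
    copies: int = 4,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Alignment sharing a planted tandem motif region over i.i.d. background.

    The motif region (its wildcard positions instantiated once) is centred in
    the alignment and copied to every sequence with per-position substitution
    probability *mutation_rate*; background columns are i.i.d. uniform per
    sequence, so they carry ~0 bits of information while planted columns are
    conserved.
    """
    k = len(motif)
    if copies * k > length:
        raise ValueError("copies * len(motif) exceeds sequence length")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    region_len = copies * k
    offset = (length - region_len) // 2
    # ancestral instantiation of the repeat region
    ancestral = []
    for _ in range(copies):
        for m in motif:
            ancestral.append(m.upper() if m not in "xX" else str(rng.choice(aa)))
    records = []
    for s in range(n_sequences):
        background = rng.choice(aa, size=length)
        seq = list(background)
        for j, res in enumerate(ancestral):
            if mutation_rate > 0 and rng.random() < mutation_rate:
                choices = [c for c in AMINO_ACIDS if c != res]
                seq[offset + j] = str(rng.choice(choices))
            else:
                seq[offset + j] = res
        records.append((f"seq{s + 1}", "".join(seq)))
    return Alignment(records=records)


def make_equilibrium_profile(
    mass: float,
    a0: float = 0.1,
    rpm: float = 28000.0,
    temperature: float = 279.15,
    vbar: float = 0.73,
    density: float = 1.005,
    r_range: tuple[float, float] = (6.95, 7.05),
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EquilibriumProfile:
    """Exponential equilibrium absorbance profile with Gaussian noise.

    ``A(r) = a0 * exp(M (1 - vbar*rho) omega^2 (r^2 - r0^2) / (2 R T))`` with
    r0 the inner radius, M in g/mol and r in cm, plus N(0, noise_sd) noise.
    """
    if mass <= 0 or a0 <= 0 or rpm <= 0 or temperature <= 0:
        raise ValueError("physical parameters must be positive")
    buoyancy = 1.0 - vbar * density
    if buoyancy <= 0:
        raise ValueError("(1 - vbar*rho) must be positive")
    rng = np.random.default_rng(seed)
    r = np.linspace(r_range[0], r_range[1], n_points)
    omega = 2.0 * math.pi * rpm / 60.0
    mass_kg = mass / 1000.0
    r_m2 = (r**2 - r_range[0] ** 2) * 1e-4  # cm^2 -> m^2
    A = a0 * np.exp(mass_kg * buoyancy * omega**2 * r_m2 / (2.0 * GAS_CONSTANT * temperature))
    if noise_sd > 0:
        A = A + rng.normal(scale=noise_sd, size=A.shape)
    return EquilibriumProfile(
        radii=r,
        absorbance=A,
        rotor_speed=rpm,
        temperature=temperature,
        vbar=vbar,
        solvent_density=density,
    )


def make_trimer_toy(
    n_spheres_per_chain: int = 8,
    packing: str = "closed",
    seed: int = 0,
) -> Structure:
    """Three sphere-chains with exact 3-fold symmetry around the z axis.

    Each chain contributes one designated *axial* sphere (residue name AXI)
    on the symmetry axis and a column of spheres (residue name COL) at radial
    distance d from the axis.  ``closed`` packing (d = 2.0 Å) fully occludes
    the axial spheres from a 1.4 Å probe; ``open`` packing (d = 6.0 Å) leaves
    them partly accessible, so the closed buried fraction strictly exceeds
    the open one.  All spheres are carbons (vdW 1.7 Å).
    """
    if n_spheres_per_chain < 2:
        raise ValueError("need at least 2 spheres per chain")
    if packing not in {"open", "closed"}:
        raise ValueError("packing must be 'open' or 'closed'")
    d = 2.0 if packing == "closed" else 6.0
    spacing = 1.0
    n_col = n_spheres_per_chain - 1
    col_z = np.arange(n_col) * spacing - (n_col - 1) * spacing / 2.0
    atoms: list[AtomRecord] = []
    serial = 0
    for i, cid in enumerate(("A", "B", "C")):
        angle = 2.0 * math.pi * i / 3.0
        # axial spheres stack contiguously at the column mid-height
        axial_z = (i - 1) * spacing
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name="C",
                element="C",
                residue_name="AXI",
                residue_number=1,
                chain_id=cid,
                position=(0.0, 0.0, float(axial_z)),
            )
        )
        for j, z in enumerate(col_z):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name="C",
                    element="C",
                    residue_name="COL",
                    residue_number=j + 2,
                    chain_id=cid,
                    position=(
                        d * math.cos(angle),
                        d * math.sin(angle),
                        float(z),
                    ),
                )
            )
    return Structure(
        atoms=atoms,
        source_id=f"synthetic-trimer-{packing}",
        title="synthetic three-fold sphere trimer",
    )
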