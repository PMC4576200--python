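"""Sequence masses, ESI mass-delta bookkeeping, and equilibrium sedimentation.

Three small pieces of biophysical arithmetic that together decide oligomeric
state and buried-cargo composition:

* protein masses from sequence (average or monoisotopic, via Biopython),
* differences between deconvoluted ESI peak masses and an "empty oligomer"
  reference, decomposed exhaustively into multisets of candidate ligand
  masses (e.g. free fatty acids), and
* single-species sedimentation-equilibrium mass fitting: at equilibrium the
  radial absorbance profile satisfies
  ``ln A(r) = const + M (1 - vbar*rho) omega^2 r^2 / (2 R T)``,
  so the least-squares slope of ln A against r^2 yields the molar mass
  ``M = 2 R T s / ((1 - vbar*rho) omega^2)``.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy import stats

__all__ = [
    "MassPeakSet",
    "DeltaDecomposition",
    "EquilibriumProfile",
    "EquilibriumFit",
    "FATTY_ACID_MASSES",
    "sequence_mass",
    "peak_deltas",
    "decompose_delta",
    "fit_equilibrium_mass",
    "oligomer_state",
    "read_mass_peak_csv",
    "read_equilibrium_csv",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
WATER_AVG = 18.02  # Da, one condensation water

#: Average masses (Da) of the free fatty acids relevant to buried-cargo
#: decomposition: palmitic C16:0, stearic C18:0, oleic C18:1.
FATTY_ACID_MASSES: dict[str, float] = {
    "palmitic": 256.43,
    "stearic": 284.48,
    "oleic": 282.46,
}


def sequence_mass(sequence: str, mode: str = "average") -> float:
    """Mass in Da of a peptide chain (residue masses + one water).

    The empty chain returns the mass of water.  *mode* selects average
    (default, the convention behind printed "calculated molecular mass"
    values) or monoisotopic masses.
    """
    if mode not in {"average", "monoisotopic"}:
        raise ValueError(f"mode must be 'average' or 'monoisotopic', got {mode!r}")
    sequence = sequence.upper()
    for i, c in enumerate(sequence):
        if c not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"illegal amino acid {c!r} at position {i}")
    if not sequence:
        return WATER_AVG if mode == "average" else 18.0106
    return float(
        molecular_weight(sequence, seq_type="protein", monoisotopic=mode == "monoisotopic")
    )


@dataclass
class MassPeakSet:
    """Deconvoluted ESI peak masses with a designated reference species."""

    peaks: list[tuple[str, float]]  # (label, mass Da)
    reference_label: str

    def __post_init__(self) -> None:
        for label, mass in self.peaks:
            if mass <= 0:
                raise ValueError(f"peak {label}: mass must be positive")
        if self.reference_label not in {lb for lb, _ in self.peaks}:
            raise KeyError(f"reference label {self.reference_label!r} not among peaks")

    def mass(self, label: str) -> float:
        for lb, m in self.peaks:
            if lb == label:
                return m
        raise KeyError(f"no peak labeled {label!r}")


def peak_deltas(peaks: MassPeakSet) -> list[tuple[str, int]]:
    """Integer mass differences (Da) of every peak against the reference."""
    ref = peaks.mass(peaks.reference_label)
    return [(label, round(mass - ref)) for label, mass in peaks.peaks]


@dataclass
class DeltaDecomposition:
    """Multisets of candidate ligands whose total mass matches a delta."""

    delta: float
    tolerance: float
    solutions: list[tuple[tuple[str, ...], float, float]] = field(default_factory=list)
    # each: (sorted candidate names, total mass, residual = delta - total)

    def __post_init__(self) -> None:
        for names, total, residual in self.solutions:
            if abs(residual) > self.tolerance + 1e-9:
                raise ValueError(f"solution {names} violates tolerance")


def decompose_delta(
    delta: float,
    candidates: Sequence[tuple[str, float]] | dict[str, float] = tuple(
        FATTY_ACID_MASSES.items()
    ),
    tolerance: float = 2.0,
    max_items: int = 3,
) -> DeltaDecomposition:
    """Exhaustively decompose a mass delta into candidate-ligand multisets.

    Every multiset of up to *max_items* candidates whose summed mass lies
    within *tolerance* Da of *delta* is returned, sorted by absolute
    residual (ties broken by name tuple).  An empty solution list is a valid
    result and documents that the delta is not a simple ligand sum.
    Residuals are kept at 0.01 Da internally.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_items < 1:
        raise ValueError("max_items must be >= 1")
    items = list(candidates.items()) if isinstance(candidates, dict) else list(candidates)
    solutions = []
    for size in range(1, max_items + 1):
        for combo in itertools.combinations_with_replacement(items, size):
            total = round(sum(m for _, m in combo), 2)
            residual = round(delta - total, 2)
            if abs(residual) <= tolerance:
                names = tuple(sorted(name for name, _ in combo))
                solutions.append((names, total, residual))
    solutions.sort(key=lambda t: (abs(t[2]), t[0]))
    return DeltaDecomposition(delta=delta, tolerance=tolerance, solutions=solutions)


@dataclass
class EquilibriumProfile:
    """A radial absorbance scan at sedimentation equilibrium."""

    radii: np.ndarray  # cm from rotor center, strictly increasing
    absorbance: np.ndarray  # AU
    rotor_speed: float  # rpm
    temperature: float  # K
    vbar: float = 0.73  # mL/g, partial specific volume
    solvent_density: float = 1.005  # g/mL (PBS-like buffer near 6 C)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radii.shape != self.absorbance.shape:
            raise ValueError("radii and absorbance must have the same shape")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return 2.0 * math.pi * self.rotor_speed / 60.0


@dataclass(frozen=True)
class EquilibriumFit:
    mass: float  # g/mol
    slope: float  # d ln A / d r^2, cm^-2
    intercept: float
    r_squared: float
    stderr_mass: float  # g/mol, from the slope standard error


def fit_equilibrium_mass(p: EquilibriumProfile) -> EquilibriumFit:
    """Molar mass from the slope of ln A against r^2.

    ``M = 2 R T s / ((1 - vbar*rho) omega^2)`` with s the least-squares
    slope (converted to m^-2), R = 8.314 J mol^-1 K^-1; result in g/mol.
    """
    if len(p.radii) < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(p.absorbance <= 0):
        raise ValueError("non-positive absorbance in fit window; trim the profile")
    buoyancy = 1.0 - p.vbar * p.solvent_density
    if buoyancy <= 0:
        raise ValueError(
            f"(1 - vbar*rho) = {buoyancy:.3f} <= 0: particle does not sediment"
        )
    res = stats.linregress(p.radii**2, np.log(p.absorbance))
    slope_m2 = res.slope * 1e4  # cm^-2 -> m^-2
    factor = 2.0 * GAS_CONSTANT * p.temperature / (buoyancy * p.omega**2)
    mass_kg = factor * slope_m2  # kg/mol (vbar*rho is dimensionless; see docs)
    stderr_kg = factor * (res.stderr or 0.0) * 1e4
    return EquilibriumFit(
        mass=mass_kg * 1000.0,
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        stderr_mass=stderr_kg * 1000.0,
    )


def oligomer_state(fitted_mass: float, monomer_mass: float) -> int:
    """Nearest integer oligomer order implied by a fitted mass."""
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    return round(fitted_mass / monomer_mass)


def read_mass_peak_csv(path: str | Path, reference_label: str) -> MassPeakSet:
    """Read ESI peak masses from CSV with columns ``label,mass_da``."""
    peaks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            peaks.append((row["label"].strip(), float(row["mass_da"])))
    return MassPeakSet(peaks=peaks, reference_label=reference_label)


def read_equilibrium_csv(
    path: str | Path,
    rotor_speed: float,
    temperature: float,
    vbar: float = 0.73,
    solvent_density: float = 1.005,
) -> EquilibriumProfile:
    """Read a radial scan from CSV with columns ``radius_cm,absorbance``."""
    radii, absorbance = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            radii.append(float(row["radius_cm"]))
            absorbance.append(float(row["absorbance"]))
    return EquilibriumProfile(
        radii=np.array(radii),
        absorbance=np.array(absorbance),
        rotor_speed=rotor_speed,
        temperature=temperature,
        vbar=vbar,
        solvent_density=solvent_density,
    )
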