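"""Reading, subsetting and writing macromolecular coordinate files.

Parsing is delegated to :mod:`gemmi`; the in-memory representation is a flat,
ordered list of :class:`AtomRecord` wrapped in a :class:`Structure`.  The flat
layout is deliberate: every downstream stage (coordination geometry, SASA,
burial) operates on per-atom arrays, not on a residue hierarchy.

Alternate locations are collapsed at parse time to the highest-occupancy
conformer (ties broken by altloc letter order) so that downstream geometry is
single-conformer and deterministic.  Residue numbering is taken verbatim from
the file; published residue ranges use author numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi

__all__ = [
    "AtomRecord",
    "Structure",
    "StructureParseError",
    "SelectionError",
    "parse_structure",
    "select_atoms",
    "write_pdb",
    "fetch_structure",
]

#: Elements treated as metals for hetero-inventory reporting.
_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class SelectionError(KeyError):
    """Raised when a selection refers to content absent from the structure."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom as deposited, with author numbering preserved."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )
        if gemmi.Element(self.element).atomic_number == 0 and self.element != "":
            raise ValueError(f"unknown element symbol {self.element!r}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES

    def distance_to(self, other: "AtomRecord") -> float:
        return math.dist(self.position, other.position)


@dataclass
class Structure:
    """An ordered collection of atoms plus light provenance metadata."""

    atoms: list[AtomRecord]
    source_id: str = ""
    title: str = ""
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chain_ids:
            seen: dict[str, None] = {}
            for a in self.atoms:
                seen.setdefault(a.chain_id, None)
            self.chain_ids = list(seen)
        missing = {a.chain_id for a in self.atoms} - set(self.chain_ids)
        if missing:
            raise ValueError(f"atoms reference chains not in chain_ids: {missing}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def elements(self) -> set[str]:
        return {a.element for a in self.atoms}

    def chain(self, chain_id: str) -> "Structure":
        return select_atoms(self, chain=chain_id)

    def residue_range(self, chain_id: str) -> tuple[int, int]:
        nums = [a.residue_number for a in self.atoms if a.chain_id == chain_id]
        if not nums:
            raise SelectionError(
                f"chain {chain_id!r} not present; available: {self.chain_ids}"
            )
        return min(nums), max(nums)

    def hetero_inventory(self) -> dict[str, int]:
        """Residue-name -> count over distinct hetero residues (waters included)."""
        seen: set[tuple[str, int, str]] = set()
        counts: dict[str, int] = {}
        for a in self.atoms:
            if a.is_hetero:
                key = (a.chain_id, a.residue_number, a.residue_name)
                if key not in seen:
                    seen.add(key)
                    counts[a.residue_name] = counts.get(a.residue_name, 0) + 1
        return counts


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # fall back on content sniffing: mmCIF starts with data_
    with open(path, "r", errors="replace") as fh:
        head = fh.read(2048)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    All ATOM and HETATM records of the first model are kept; waters are
    retained (residue name normalised upstream by the depositor, not here);
    alternate locations are collapsed to the highest-occupancy conformer.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (extension, then content sniff).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise StructureParseError(f"empty coordinate file: {path}")
    fmt = _detect_format(path, format)
    if fmt not in {"pdb", "mmcif"}:
        raise StructureParseError(f"unknown format {format!r} (use pdb/mmcif/auto)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    serial = 0
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no coordinate model")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in _collapse_altlocs(residue):
                serial += 1
                element = atom.element.name if atom.element.name != "X" else ""
                if not element:
                    element = _element_from_name(atom.name, residue.name)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        is_hetero=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(
        atoms=atoms,
        source_id=st.name or path.stem,
        title=dict(st.info).get("_struct.title", ""),
    )


def _collapse_altlocs(residue: gemmi.Residue) -> Iterable[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ or (
            atom.occ == prev.occ and _altloc_key(atom) < _altloc_key(prev)
        ):
            by_name[atom.name] = atom
    return (by_name[n] for n in order)


def _altloc_key(atom: gemmi.Atom) -> str:
    alt = atom.altloc
    return "~" if alt in ("", "\x00") else alt


def _element_from_name(atom_name: str, residue_name: str) -> str:
    """Infer element from the atom name; failure is a hard error, never carbon."""
    stripped = atom_name.strip()
    if residue_name in _WATER_NAMES:
        return "O"
    # two-letter ion names like MG, CA (as residue CA ion), NA, ZN, FE
    if stripped == residue_name.strip() and gemmi.Element(stripped.capitalize()).atomic_number:
        return stripped.capitalize()
    for probe in (stripped[:2].capitalize(), stripped[:1].upper()):
        if probe and gemmi.Element(probe).atomic_number:
            # prefer single-letter organic elements for standard PDB names
            if len(stripped) <= 3 and stripped[0] in "CNOSHP":
                return stripped[0].upper()
            return probe
    raise StructureParseError(
        f"cannot infer element for atom {atom_name!r} in residue {residue_name!r}"
    )


def select_atoms(
    s: Structure,
    chain: Optional[str] = None,
    residue_range: Optional[tuple[int, int]] = None,
    element: Optional[str] = None,
    hetero_only: bool = False,
) -> Structure:
    """Return a sub-Structure preserving atom order.

    An empty selection is a valid empty Structure; a *chain* that does not
    exist at all raises :class:`SelectionError` listing the available chains.
    """
    if chain is not None and chain not in s.chain_ids:
        raise SelectionError(
            f"chain {chain!r} not present; available chains: {s.chain_ids}"
        )
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"residue_range {residue_range} is not ordered")
    picked = []
    for a in s.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        if element is not None and a.element.capitalize() != element.capitalize():
            continue
        if hetero_only and not a.is_hetero:
            continue
        picked.append(a)
    return Structure(
        atoms=picked,
        source_id=s.source_id,
        title=s.title,
        chain_ids=[c for c in s.chain_ids if any(a.chain_id == c for a in picked)],
    )


def to_gemmi(s: Structure, name: str = "model") -> gemmi.Structure:
    """Build a gemmi Structure (single model) from a :class:`Structure`."""
    st = gemmi.Structure()
    st.name = s.source_id or name
    model = gemmi.Model("1")
    for cid in s.chain_ids:
        chain = gemmi.Chain(cid)
        # group consecutive atoms of the same residue; gemmi containers
        # copy on add, so each residue must be complete before add_residue
        groups: list[tuple[tuple[int, str], list[AtomRecord]]] = []
        for a in s.atoms:
            if a.chain_id != cid:
                continue
            key = (a.residue_number, a.residue_name)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        for (resnum, resname), members in groups:
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(resnum, " ")
            residue.het_flag = "H" if members[0].is_hetero else "A"
            for a in members:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                atom.altloc = a.altloc or "\x00"
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (via gemmi)."""
    to_gemmi(s).write_pdb(str(path))


def fetch_structure(
    pdb_id: str, cache_dir: str | Path, timeout: float = 10.0
) -> Structure:
    """Fetch a deposited model by 4-character PDB id, caching the file locally.

    Looks for ``<cache_dir>/<ID>.pdb`` first; otherwise downloads from the
    RCSB file server.  Network failures propagate (``URLError``/``OSError``)
    so callers can distinguish "offline" from "bad id".
    """
    import urllib.request

    pdb_id = pdb_id.upper()
    cache_dir = Path(cache_dir)
    local = cache_dir / f"{pdb_id}.pdb"
    if not local.exists():
        cache_dir.mkdir(parents=True, exist_ok=True)
        url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            local.write_bytes(resp.read())
    return parse_structure(local, format="pdb")


def chain_sequence(s: Structure, chain_id: str) -> str:
    """One-letter amino-acid sequence of a chain's polymer residues.

    Residues are taken in file order, one letter per distinct residue number;
    non-standard residues map to ``X``; waters and hetero compounds are
    skipped.
    """
    letters: list[str] = []
    seen: set[int] = set()
    for a in s.atoms:
        if a.chain_id != chain_id or a.is_hetero or a.is_water:
            continue
        if a.residue_number in seen:
            continue
        seen.add(a.residue_number)
        info = gemmi.find_tabulated_residue(a.residue_name)
        code = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
        letters.append(code if code.isalpha() else "X")
    return "".join(letters)


def format_info_tsv(s: Structure) -> str:
    """Chains, residue ranges and hetero inventory as TSV (CLI `fetch-info`)."""
    lines = ["kind\tname\tfirst\tlast\tn_atoms"]
    for cid in s.chain_ids:
        sub = [a for a in s.atoms if a.chain_id == cid]
        lo, hi = s.residue_range(cid)
        lines.append(f"chain\t{cid}\t{lo}\t{hi}\t{len(sub)}")
    for resname, count in sorted(s.hetero_inventory().items()):
        lines.append(f"hetero\t{resname}\t.\t.\t{count}")
    return "\n".join(lines) + "\n"
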