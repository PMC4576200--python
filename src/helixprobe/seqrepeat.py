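"""Tandem repeat detection and alignment-column profiling for beta-helices.

gp5-like triple-stranded beta-helices tile an eight-residue motif, VxGxxxxx,
whose copies define the structural rungs of the helix.  This module scans
ungapped sequences for maximal tandem runs of such a wildcard motif and
builds per-column profiles over a homolog alignment:

* residue frequencies and Shannon information content (bits), the quantity a
  sequence logo draws as letter height, and
* mean side-chain size counted in non-hydrogen atoms, the quantity used to
  compare interior packing along the helix.

Side-chain heavy atoms are counted beyond the C-alpha: Gly = 0, Ala = 1
(the C-beta), ..., Trp = 10.  Gaps are excluded from both the frequency
normalisation and the size mean; the gap fraction is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = [
    "Alignment",
    "PositionProfile",
    "RepeatHit",
    "SIDECHAIN_HEAVY_ATOMS",
    "GP5_HOMOLOG_ACCESSIONS",
    "read_alignment",
    "find_repeats",
    "sidechain_size_profile",
    "information_content_profile",
    "profile_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."

#: Non-hydrogen atoms beyond the C-alpha, per residue.
SIDECHAIN_HEAVY_ATOMS: dict[str, int] = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 3, "V": 3, "P": 3,
    "I": 4, "L": 4, "N": 4, "D": 4, "M": 4,
    "E": 5, "Q": 5, "K": 5, "H": 6, "R": 7, "F": 7, "Y": 8, "W": 10,
}

#: GenBank protein accessions of the gp5 homologs used for the packaged
#: conservation analysis (phage name -> accession).
GP5_HOMOLOG_ACCESSIONS: dict[str, str] = {
    "T4": "NP_049757.1",
    "Escherichia phage ECML-134": "YP_009102621.1",
    "Yersinia phage PST": "AGR46096.1",
    "Escherichia phage wV7": "YP_007004892.1",
    "Enterobacteria phage RB3": "YP_009098534.1",
    "Enterobacteria phage RB51": "YP_002854107.1",
    "Enterobacteria phage AR1": "BAI83163.1",
    "Enterobacteria phage IME09": "YP_007004528.1",
    "Shigella phage Shfl2": "YP_004415044.1",
    "Enterobacteria phage RB32": "YP_803092.1",
    "Enterobacteria phage RB14": "YP_002854485.1",
    "Enterobacteria phage vB_EcoM_ACG-C40": "YP_006986702.1",
    "Yersinia phage phiD1": "CCI89046.1",
    "Enterobacteria phage vB_EcoM_VR20": "AIZ02221.1",
    "Enterobacteria phage vB_EcoM-VR7": "YP_004063846.1",
    "Enterobacteria phage vB_EcoM_VR26": "AIZ02797.1",
    "Enterobacteria phage vB_EcoM_VR25": "AIZ02510.1",
    "Enterobacteria phage vB_EcoM_VR5": "AIZ01937.1",
    "Enterobacteria phage JS10": "YP_002922494.1",
    "Enterobacteria phage IME08": "YP_003734291.1",
    "Enterobacteria phage JS98": "YP_001595278.1",
    "Salmonella phage S16": "YP_007501180.1",
    "Salmonella phage STML-198": "AFU64090.1",
    "Escherichia phage vB_EcoM_JS09": "YP_009037344.1",
    "Shigella phage Shf125875": "YP_009100697.1",
    "Escherichia phage vB_EcoM_PhAPEC2": "YP_009056740.1",
    "Enterobacter phage PG7": "YP_009005432.1",
    "Enterobacteria phage CC31": "YP_004010012.1",
    "Enterobacteria phage RB69": "NP_861854.1",
    "Yersinia phage phiR1-RT": "YP_007235983.1",
    "Acinetobacter phage 133": "YP_004300735.1",
    "Acinetobacter phage Ac42": "YP_004009522.1",
    "Shigella phage SP18": "YP_003934787.1",
    "Enterobacteria phage Bp7": "YP_007004296.1",
    "Acinetobacter phage Acj9": "YP_004010297.1",
    "Acinetobacter phage ZZ1": "YP_006489164.1",
    "Acinetobacter phage Acj61": "YP_004009776.1",
}


@dataclass
class Alignment:
    """A validated multiple sequence alignment over amino acids + gap."""

    records: list[tuple[str, str]]  # (id, aligned sequence)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        length = len(self.records[0][1])
        self.records = [(rid, seq.upper()) for rid, seq in self.records]
        for rid, seq in self.records:
            if len(seq) != length:
                raise ValueError(
                    f"record {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - set(AMINO_ACIDS) - set(GAP_CHARS) - {"X"}
            if bad:
                raise ValueError(f"record {rid!r} contains illegal symbols {sorted(bad)}")
        self.has_unknown = any("X" in seq for _, seq in self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)


@dataclass
class PositionProfile:
    """Per-column channels over an alignment (NaN where a column is all-gap)."""

    frequencies: list[dict[str, float]]
    information: np.ndarray  # bits
    mean_sidechain_atoms: np.ndarray
    gap_fraction: np.ndarray
    all_gap: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        if self.all_gap is None:
            self.all_gap = np.isnan(self.information)


@dataclass(frozen=True)
class RepeatHit:
    """A maximal tandem run of a motif: [start, start + copies*len(motif))."""

    start: int  # 0-based
    copies: int
    motif_length: int

    @property
    def end(self) -> int:
        return self.start + self.copies * self.motif_length


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and validate a FASTA or Clustal alignment."""
    if format not in {"fasta", "clustal"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"missing or empty alignment file: {path}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    return Alignment(records=[(rec.id, str(rec.seq)) for rec in msa])


def _motif_matches(sequence: str, motif: str, pos: int) -> bool:
    if pos + len(motif) > len(sequence):
        return False
    for m, s in zip(motif, sequence[pos : pos + len(motif)]):
        if m not in ("x", "X") and m != s:
            return False
    return True


def find_repeats(sequence: str, motif: str = "VxGxxxxx", min_copies: int = 2) -> list[RepeatHit]:
    """Maximal tandem runs of *motif* (wildcard ``x``) in an ungapped sequence.

    Runs are maximal: they cannot be extended by another whole motif copy on
    either side.  Runs whose intervals overlap are merged into the earlier
    run's frame (the later, shifted frame is dropped), so reported hits never
    overlap.  Coordinates are 0-based half-open.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    sequence = sequence.upper()
    k = len(motif)
    hits: list[RepeatHit] = []
    for start in range(len(sequence) - k * min_copies + 1):
        if hits and start < hits[-1].end:
            continue  # inside the previous maximal run: same or shifted frame
        copies = 0
        pos = start
        while _motif_matches(sequence, motif, pos):
            copies += 1
            pos += k
        if copies >= min_copies:
            hits.append(RepeatHit(start=start, copies=copies, motif_length=k))
    return hits


def _column_stats(column: str) -> tuple[dict[str, float], float, float, float]:
    residues = [c for c in column if c in AMINO_ACIDS]
    n_gap = sum(1 for c in column if c in GAP_CHARS)
    gap_fraction = n_gap / len(column)
    if not residues:
        return {}, math.nan, math.nan, gap_fraction
    freqs: dict[str, float] = {}
    for c in residues:
        freqs[c] = freqs.get(c, 0.0) + 1.0
    total = sum(freqs.values())
    freqs = {c: v / total for c, v in freqs.items()}
    entropy = -sum(p * math.log2(p) for p in freqs.values())
    information = math.log2(20) - entropy
    size = float(np.mean([SIDECHAIN_HEAVY_ATOMS[c] for c in residues]))
    return freqs, information, size, gap_fraction


def _build_profile(a: Alignment) -> PositionProfile:
    freqs, info, size, gaps = [], [], [], []
    for i in range(a.length):
        f, b, s, g = _column_stats(a.column(i))
        freqs.append(f)
        info.append(b)
        size.append(s)
        gaps.append(g)
    return PositionProfile(
        frequencies=freqs,
        information=np.array(info),
        mean_sidechain_atoms=np.array(size),
        gap_fraction=np.array(gaps),
    )


def sidechain_size_profile(a: Alignment) -> PositionProfile:
    """Per-column mean side-chain heavy-atom count over non-gap residues.

    Columns containing only gaps carry NaN in the size channel and are
    flagged in ``all_gap``.  ``X`` residues are excluded from the mean.
    """
    return _build_profile(a)


def information_content_profile(a: Alignment) -> PositionProfile:
    """Per-column Shannon information log2(20) - H over non-gap residues.

    No small-sample correction is applied; a fully conserved column scores
    log2(20) ~ 4.32 bits, a uniform column 0 bits.
    """
    return _build_profile(a)


def profile_table(a: Alignment) -> str:
    """TSV with columns: column, gap_fraction, bits, mean_size."""
    prof = _build_profile(a)
    lines = ["column\tgap_fraction\tbits\tmean_size"]
    for i in range(a.length):
        b = prof.information[i]
        s = prof.mean_sidechain_atoms[i]
        lines.append(
            f"{i}\t{prof.gap_fraction[i]:.3f}\t"
            f"{'NA' if math.isnan(b) else f'{b:.3f}'}\t"
            f"{'NA' if math.isnan(s) else f'{s:.3f}'}"
        )
    return "\n".join(lines) + "\n"
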