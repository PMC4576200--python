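# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each analysis stage. It states no empirical result that
the test suite does not itself compute.

## Coordinate handling

Structures are parsed with gemmi (PDB and mmCIF) into a flat list of atom
records. Alternate locations are collapsed at parse time to the
highest-occupancy conformer, ties broken by altloc letter order, so that all
downstream geometry is single-conformer and deterministic. Residue numbers
are kept exactly as deposited (author numbering): published residue ranges
such as 483–575 refer to that numbering and renumbering would silently break
them. Hydrogens, when present, are carried in the structure but excluded
from geometry and SASA (crystal structures at the relevant resolutions have
none). Element symbols come from the element column; when it is absent they
are inferred from atom-name conventions, and an uninferrable name is a hard
error rather than a guess to carbon.

## Buried-metal coordination geometry

A candidate site is a single-atom hetero record of a common biological metal
(Na, Mg, K, Ca, Mn, Fe, Co, Ni, Cu, Zn, Sr) with at least four O/N atoms
within the inner cutoff. Cutoffs: inner shell ≤ 3.0 Å (spans direct
metal–O/N bonds, 1.8–2.9 Å, with margin), outer shell 3.0–4.5 Å (second
hydration sphere). Ligands are restricted to O and N to exclude incidental
carbon contacts. Shell distances are summarised as mean ± *population*
standard deviation, reported to 0.01 Å — the convention behind "2.16 ± 0.06 Å"
style figures with n = 6.

"Deviation from a perfect octahedron" is ambiguous, so two metrics are
computed and reported side by side:

* **edge_rmsd** — the 15 ligand–ligand distances, partitioned into 12 cis
  pairs (ideal √2·r) and 3 trans pairs (ideal 2·r) by the center angle
  (< 135° → cis), compared with the ideal values for r = mean center–ligand
  distance. The angle partition is unambiguous for distortions well below
  the shell radius; a partition that does not yield exactly 3 trans pairs is
  reported as an error rather than forced.
* **position_rmsd** — least-squares superposition of an ideal octahedron of
  radius r onto the six ligand positions. The vertex correspondence is
  derived from the trans pairing (each trans pair ↔ one ± axis) and the
  proper rotation minimised by Kabsch over all 48 assignments consistent
  with that pairing. The test suite verifies this against a brute-force
  rotation-grid search with bipartite vertex matching, to 10⁻³ Å.

Metal identity is ranked by z = (observed mean − reference mean)/reference SD
against a reference table of metal–water bond lengths. The Mg²⁺ and Ca²⁺
rows are the MESPEUS_10 survey values (2.17 ± 0.15 Å and 2.46 ± 0.22 Å); the
Na⁺, K⁺, Zn²⁺, Mn²⁺ and Sr²⁺ rows are representative values from the same
family of PDB distance surveys and are flagged by their source string.

**Limitation.** Bond distance alone cannot separate metals whose water-O
distances differ by less than the shell spread — Mg²⁺ (2.17 Å), Mn²⁺
(2.19 Å) and Zn²⁺ (2.09 Å) overlap heavily. The ranking is meaningful for
discriminating between candidates with distinct radii (the Mg-vs-Ca
question); for near-degenerate candidates the z-scores document the
ambiguity instead of resolving it, and the test suite asserts rank-1
recovery only across the distinguishable MESPEUS pair (top-2 across the
full table).

## Anomalous scattering and Bijvoet-difference calibration

f′(E) and f″(E) are tabulated at import time from the Cromer–Liberman
theory as implemented in gemmi, on a 0.05 keV grid over 6–18 keV with
absorption-edge energies inserted as explicit breakpoints (the Sr K edge at
16.105 keV falls inside the range), so linear interpolation never crosses an
edge. Wavelengths convert to energy as E[keV] = 12.398/λ[Å]. Lookups are
reported to two decimals.

A Bijvoet-difference Fourier peak's height is proportional to
occupancy × f″ at equal displacement parameters, so internal sulfur atoms at
full occupancy calibrate the map. The occupancy estimate is

    occ = (target height / mean reference height) / (f″(metal)/f″(S))

using the arithmetic mean of the sulfur references (configurable). Every
estimate carries its assumptions explicitly — equal B-factors, common map
scale, references at full occupancy — because B-factor differences bias the
heights and are not corrected for. Estimates above 1.2 are flagged
inconsistent, never clamped. Candidate verdicts use a detection floor of
0.5× the mean reference peak: an element whose full-occupancy expectation
falls below that floor cannot explain a peak exceeding the references.

## Toy anomalous crystals

The generator builds a P1 orthorhombic cell and computes F(+h) and F(−h) by
direct summation with complex scattering factors f₀ + f′ + i·f″ (f₀ from the
standard 4-Gaussian approximation, per element). The Bijvoet-difference
synthesis uses the standard coefficients (|F⁺| − |F⁻|)·exp(i(φ − 90°)) with
φ the phase of the non-anomalous model, evaluated on an FFT grid of at most
64³; peak heights are refined off-grid by local search of the direct
synthesis so they do not depend on atoms sitting on grid points. Map sigma
is the standard deviation over grid points more than 2 Å from any atom.

Two regime constraints matter and are deliberately part of the design:

* Bijvoet differences arise from interference between anomalous and normal
  scatterers; a cell containing only the anomalous atoms yields a
  degenerate (near-zero or ghost-dominated) map.
* The standard synthesis carries a second-order term that coherently
  *suppresses* each anomalous peak in proportion to that atom's (and its
  partners') share of the total normal scattering. Peak heights track
  occupancy × f″ only in the dilute regime — thousands of light atoms per
  anomalous site, as in a real protein crystal.

The generator therefore accepts a seeded light-atom bulk (`background_atoms`
uniform random carbons; ~3000 for quantitative ratio tests). Atom overlap
in the random bulk is irrelevant to the interference statistics. Heights in
sigma units saturate at high planted occupancy because the map noise itself
grows with the anomalous signal; linearity in occupancy holds for absolute
map values and for sulfur-calibrated ratios, which is what the tests assert.

## Solvent-accessible surface and burial

SASA uses the Shrake–Rupley rolling-probe algorithm with a golden-spiral
point mesh (default 960 points/atom, probe 1.4 Å) and Bondi-family van der
Waals radii with the usual protein-atom extension (C 1.70, N 1.55, O 1.52,
S 1.80 Å …). Waters and hetero ligands are excluded by default (the
protein-interface convention); an unknown element is an error naming the
element. Neighbour search uses a k-d tree; accuracy improves roughly as
1/points and the suite checks < 0.5% drift on point doubling plus agreement
with the isolated- and two-sphere closed forms and with an independent
Shrake–Rupley implementation.

Per-chain burial compares the chain computed alone with its contribution
inside the complex: buried = SASA(alone) − SASA(in complex), fraction
reported to a whole percent. Interface servers use related but not
identical algorithms and radii; totals can differ by a few percent, which
is why the deposited-model burial check carries a ±3 percentage-point
tolerance.

## Repeats and alignment profiles

The β-helix motif is scanned as a wildcard pattern (fixed letters plus `x`)
over ungapped sequence; maximal tandem runs of at least `min_copies` are
reported 0-based half-open, and shifted overlapping frames are merged into
the earlier run so hits never overlap.

Column profiles exclude gaps from both frequency normalisation and size
means (gap fraction is reported separately): the profiles describe residue
properties, not column occupancy. Information content is log₂20 − H with no
small-sample correction. Side-chain size counts non-hydrogen atoms beyond
the Cα — Gly = 0, Ala = 1 (the Cβ), …, Trp = 10; this "beyond Cα" convention
is a declared choice, since counts including the backbone would simply add a
constant 4. All-gap columns are flagged and carry NaN. An optional
user-supplied column mask supports restricting profiles to inward-pointing
positions, because the inward/outward assignment comes from structure, not
sequence. The accession list of the 37 gp5 homologs used for conservation
analysis ships as packaged metadata.

## Masses and sedimentation equilibrium

Sequence masses are residue masses plus one water (Biopython's standard
tables); average masses are the default because printed "calculated
molecular mass" figures use them. ESI deltas are integer Da against a
designated empty-oligomer reference peak, matching the precision of
deconvoluted peak lists; decomposition residuals are kept at 0.01 Da
internally. Delta decomposition enumerates all candidate multisets up to
`max_items` exhaustively (the default candidate set is the three free fatty
acids: palmitic 256.43, stearic 284.48, oleic 282.46 Da) — an empty solution
list is itself informative, documenting that a delta is not a simple ligand
sum.

Sedimentation equilibrium assumes a single ideal species, for which
ln A(r) is linear in r²; the molar mass is M = 2RT·s/((1 − v̄ρ)ω²) with the
least-squares slope s converted to SI. Defaults: v̄ = 0.73 mL/g and solvent
density 1.005 g/mL (phosphate-buffered saline near 6 °C; the buffer
composition fixes ρ only approximately, so it is configurable). No
multi-component or association models are fitted: single-slope plots do not
constrain them.

## Synthetic-data conditions

Generator defaults encode the study conditions the stages are meant to
handle: hydrated sites with six inner waters at 2.16 Å and three outer at
4.21 Å; equilibrium scans at 28,000 rpm, 279.15 K, v̄ 0.73, 50 points over
6.95–7.05 cm with absorbance 0.1–0.8 AU (a realistic absorbance-optics
window) and Gaussian noise of 0.005 AU; alignments of 20 sequences with a
centred planted repeat over i.i.d. uniform background; toy crystals at 1 Å
resolution in a 12 Å cell. All generators are deterministic under a fixed
seed.

What the generators do *not* emulate: real crystallographic error models
(the toy maps are noise-free apart from the synthesis's own ghost term),
sequence phylogeny (homolog columns are i.i.d. given the ancestor, so
conservation scores are sharper than in real alignments), solution
non-ideality in sedimentation, and real β-helix backbone geometry (the
trimer toy is spheres with exact 3-fold symmetry). Passing tests therefore
demonstrate correctness of the estimators under their stated model
assumptions, not robustness to every artefact of real data.

## Deposited-model checks

The checks against the deposited 1.3 Å trimer model (shell statistics,
octahedral deviation, interface burial, monomer mass) require the 4JJ2
coordinate file, cached under `tests/data/` or downloaded on demand; they
fail with instructions when the file is unavailable rather than passing
vacuously. The published octahedral deviation (0.25 Å) does not state
whether it was computed over edge lengths or fitted vertex positions, so the
check accepts either metric. The monomer-mass check prepends the Gly-Ser
thrombin-cleavage remnant of the expression construct to the modelled
sequence; whether the printed calculated mass includes those vector residues
is not documented, and the tolerance reflects that.
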