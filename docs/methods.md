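# Methods

This note documents the models, conventions and numerical choices behind
`ssfold`, and what the synthetic generators do and do not emulate.

## Coordinate handling

PDB files are parsed with gemmi into a minimal ensemble container: an
ordered list of models, each a chain → residue list keyed by author residue
numbers (the numbering used in published disulfide-pair labels).  One model
is created per MODEL record, a single implicit model otherwise; all models
of a file must share the same (chain, seq_id, res_name) set or parsing
fails.  Alternate locations are resolved to the highest-occupancy conformer
with an alphabetical tie-break, hydrogens and waters are dropped, and
HETATM records are kept only for nonstandard amino acids within a chain.
The writer emits fixed-width ATOM records at the format's native 10⁻³ Å
precision, which bounds round-trip fidelity: quantities re-measured from a
written file can drift at the third decimal (visible as ~0.003 kJ/mol in
strain energies of fixtures).

Torsions follow the IUPAC sign convention (cis = 0°, range (−180°, 180°]),
computed by the projection formulation and cross-checked in the tests
against an independent normals-based oracle and against biotite.

## Disulfide strain

The Katz–Kossiakoff cosine series over the five cystine torsions estimates
conformational strain in kJ/mol.  Its coefficients (8.37, 4.18, 14.64,
2.51) sum to an upper bound of 84.50 kJ/mol at the all-eclipsed geometry;
because the 2χ3 and 3χ3 terms cannot vanish simultaneously, the attainable
minimum is ≈ 2.04 kJ/mol near |χ3| ≈ 83°, with the other torsions
staggered.  Since the four χ1/χ2 terms are independently minimizable, the
global minimum is found exactly by a 1-D sweep of χ3 — the acceptance
script does this at 0.01° resolution.

Bridge detection uses an SG–SG cutoff of 2.3 Å (covalent S–S ≈ 2.05 Å plus
coordinate noise), greedy by ascending distance so each sulfur joins at
most one bridge.  Ensemble summaries take the first `n_lowest = 10` models
in file order: NMR depositions conventionally deposit conformers best
first, and deposited files carry no energies to sort by.  Spread is the
sample (n−1) standard deviation, forced to exactly 0 for degenerate
(all-identical or single-model) ensembles.  Both choices are tolerance
sources when comparing against values computed by other software with
unknown model selection and SD conventions.

## Helix axes

The local axis of four consecutive Cα atoms is the unit cross product of
the two second differences of the window — for a regular helix both second
differences point toward the axis, so their cross product is parallel to
it.  Axes are oriented along the chain direction and averaged (unit-mean)
into a per-segment global axis; a near-zero mean signals a kinked segment
that should be split.  Segment boundaries are caller inputs (experimental
helix assignments), not auto-detected.  Two segments are compared as
undirected lines, arccos|u·v| ∈ [0°, 90°]: hairpin helices run
antiparallel, and the field reports their axial angle as the small
undirected value, not ~180° minus it.

A note on the PCA cross-check used in the tests: the principal component
of a helical Cα cloud converges on the true axis only once the helix is
several turns long (the 2.3 Å spiral radius tilts the first component by
~9° for a 2-turn helix, ~1° beyond 6 turns), so the cross-method agreement
test uses a 22-residue helix.

## Ramachandran classification

φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1); termini carry an undefined angle
on the missing side.  Classification uses a 10°×10° grid built
programmatically from axis-aligned polygon pieces approximating the
data-derived Procheck regions: core A (right-handed helix), B (β, wrapping
across ψ = ±180°) and a tight L (left-handed helix); an additional-allowed
envelope around them; and a generous class formed by dilating the allowed
envelope by 20° with wraparound.  Everything else is disallowed.  Summary
percentages are computed over non-glycine, non-proline, non-terminal
residues, to one decimal.  Exact region masks at finer resolution vary
between implementations; agreement with other tools should be expected to
±1 residue of classification, which for a 32-residue count is ~3 %.

## Superposition

Kabsch least squares via SVD with reflection correction (determinant
forced to +1), RMSD over the transformed pairs.  Segment RMSD maps
residues positionally within caller-stated ranges (no sequence alignment),
concatenates all segments' backbone atoms (default N, CA, C, O;
configurable to N, CA, C) and performs one joint superposition, returning
the single global RMSD.  The tests check it against an independent Horn
quaternion implementation to 10⁻⁹ Å.

## Digest-mass connectivity

Masses are neutral monoisotopic Da throughout (inputs are assumed
deconvoluted): standard residue masses plus one water (18.010565 Da) per
peptide, minus 2.015650 Da (two hydrogens) per disulfide.  Pepsin
specificity is implemented as cleavage after every Phe and Leu — its
near-exclusive specificity at pH ≈ 1.4 — with the common "not before Pro"
refinement available but off by default; `max_missed = 2` by default
because a 41-mer with eight sites digests incompletely in practice.
Candidate connectivities are all perfect matchings of the cysteines
((2k)!/(k!·2^k) of them).  For each, every hypothesis pair whose cysteines
fall in two distinct fragments yields a two-fragment crosslinked species
(bonds aggregated when two pairs join the same fragments); intra-fragment
pairs decrement that fragment's mass.  Observed masses are matched greedily
(best ppm first, each observation and each species consumed once) within a
10 ppm default tolerance, and hypotheses are ranked by matches then mean
|ppm|, with exact ties flagged ambiguous.  Charge states, isotope
envelopes and MS/MS fragmentation are out of scope.

## Spectra

MRE conversion is the exact arithmetic (θ·100)/(l·C·N).  Blank subtraction
linearly interpolates the blank onto the sample grid over the overlap.
Band centers come from a Savitzky–Golay-smoothed curve (default 7 points,
order 3) with the discrete maximum refined by a least-squares parabola
over ±8 grid points.  The wide parabola is deliberate: with a 1 cm⁻¹ grid
and amide-I-width bands, a 3-point parabola transmits grid noise almost
unattenuated and misses sub-wavenumber accuracy at realistic
signal-to-noise, while the ±8-point fit recovers a constructed 36 cm⁻¹
shift to better than 1 cm⁻¹ at SNR 20.  Full band-shape fitting and
Fourier self-deconvolution are intentionally absent — peak positions, not
component areas, are the quantity of interest here.  Isotope-shift
assignment accepts 30–45 cm⁻¹ (the canonical ¹³C helix shift of ~35–40
cm⁻¹ with margin) as "α-helix (¹³C-shifted)"; shifts below that window are
flagged ambiguous because they overlap β-sheet positions.  β-sheet content
is reported only qualitatively; CD secondary-structure deconvolution is
out of scope.

## Synthetic generators

All builders are pure functions of (spec, seed) using one geometric
primitive: NeRF internal-coordinate placement, which realizes specified
torsions exactly and makes build→measure inversion identities the backbone
of the test suite.  Ideal helices use rise 1.5 Å, twist 100°/residue,
Cα radius 2.3 Å (Cα-only mode) or standard backbone bond geometry at
φ = −57°, ψ = −47°, ω = 180° (full-backbone mode).  Cystine fixtures use
C–S 1.81 Å, S–S 2.05 Å (the distance constraint used when refining the SMB
model) and 114°/104° angles.  Hairpins place two helices at an exact
undirected axis angle joined by a jittered coil linker.  Spectra are
Gaussian band sums with additive Gaussian noise; digest observations are
theoretical species masses with uniform ppm jitter and seeded dropout.

What the generators do *not* emulate: real coordinate error and thermal
disorder, helix fraying and irregularity, overlapping amide-I component
band shapes, baseline drift, incomplete or nonspecific proteolysis, and
detector noise correlation.  Passing tests therefore demonstrate
correctness of the computations and their inverses under controlled
conditions, not robustness to every artifact of experimental data.

## Problem sizes

The default test and acceptance runs use 8–41-residue chains, ensembles of
≤10 models, 50-seed property sweeps and 20-seed recovery sweeps — sizes
chosen to match the peptide systems the package targets, where every
analysis completes in well under a second.

## Known limitations

- Printed-value comparisons against deposited PDB entries and the
  supplementary SMB/SP-B models require the user to supply those files
  (`data/external/`); they are not redistributed.
- The Procheck-style region grid is an approximation; classification near
  region boundaries can differ from other software by one cell.
- Residue-numbering offsets between depositions and published pair labels
  must be resolved by the caller (pairs are addressed by author numbering).
- mmCIF input is not supported; the PDB dialect is required.
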