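# Methods

This note records the models, numerical choices and limitations behind
`structfig`, in the order the pipeline runs.

## Structure model and PDB dialect

Structures live in a model → chain → residue → atom hierarchy of plain
dataclasses. Parsing is strictly column-positional against the wwPDB v3.3
fixed columns; only ATOM/HETATM records are interpreted, MODEL/ENDMDL
delimit models, and the first model is loaded unless another index is
requested — batch jobs therefore never depend on trailing models. HETATM
atoms are parsed but flagged and excluded from CA traces and alignment by
default (they are "decoration", not fold). Altloc ties keep the
first-listed conformer; insertion codes participate in residue identity
and ordering but have no selection-grammar syntax. mmCIF, MMTF and
trajectories are out of scope; PDB is the single dialect.

Writing quantizes coordinates to 3 decimals and B-factors to 2 — the
field widths of the format. The fixture generators quantize to the same
precision, which is what makes the read → write → read round trip exactly
lossless in tests. The B-factor column doubles as the carrier for
per-residue distances or attribute values, a long-standing community
convention that keeps colored structures viewable in any PDB viewer.

## Residue correspondence

All scores require a pairing first. `strict` mode demands equal-length CA
traces with identical residue-name sequences (the natural mode for
conformers and predicted models of one sequence) and fails loudly at the
first mismatch; `by-number` intersects (chain_id, res_seq) keys for
truncated or windowed variants. Sequence-alignment-driven pairing of
non-identical proteins is deliberately out of scope. A correspondence
shorter than 3 pairs is rejected: the rigid superposition would be
underdetermined.

## Superposition and scores

**Kabsch.** The least-squares rotation comes from the SVD of the 3×3
cross-covariance of the centered point sets; if the optimal orthogonal
map is a reflection, the singular direction of smallest singular value is
flipped, so the returned matrix is always a proper rotation (det +1 to
1e-8). Point sets of rank < 2 (collinear) are rejected rather than
silently resolved. Unit tests check optimality against an exhaustive
Euler-angle grid: the closed form must never lose to any grid rotation.

**GDT and TM both maximize over superpositions**, which has no closed
form. The search used here is seed-and-refine: least-squares fits seeded
on every contiguous CA window of length 3, 5 and 7 plus the full-length
fit; each seed is refined by refitting on the residues currently inside
the inclusion threshold (d ≤ cutoff for GDT, d < d0 for TM) until the
inclusion set stops changing, capped at 10 rounds. Every intermediate
pose is kept as a candidate, so the reported score is by construction at
least the plain full-length fit's score. This is a deterministic
heuristic in the spirit of the LGA/TM-score iterative fits, not
TM-align's dynamic-programming search; on heavily distorted pairs it can
undershoot the true maximum, which biases scores conservatively.

GDT cutoffs are the standard 1/2/4/8 Å (TS) and 0.5/1/2/4 Å (HA),
reported as percentages (25·Σf). The TM normalization distance is
d0 = 1.24·(L_norm − 15)^⅓ − 1.8 Å with L_norm defaulting to the
reference length; d0 is floored at 0.5 Å because the raw formula reaches
zero near L_norm ≈ 18 and goes negative below (for L_norm = 20 the raw
value is ≈ 0.32 Å).

**One display pose per pair.** Even when GDT/TM search other poses, the
transform stored in the result — and used for per-residue distances,
B-factor export and rendering — is the RMSD-optimal one. This keeps
`mean(per_residue_distance²) = rmsd²` as an internal identity and gives
downstream coloring and rendering a single canonical pose.

**Batching** is contractually bitwise-equal to the sequential loop;
prerequisite failures are collected per item instead of aborting the
batch. The implementation simply runs the loop — any future vectorized
fast path must preserve the equality.

## Selection language

One expression = one level keyword + a target list; the result is the
union over targets of all atoms of matched elements. Composition
(intersection, union, difference) happens on the returned sets, which is
the extension point instead of a boolean grammar. Choices where the
grammar itself is silent: `position` matches res_seq in any chain
(restrict by intersecting with a `chain:` selection); residue- and
atom-name matching is case-insensitive exact, with no wildcards;
`segment` maps to the PDB segID columns 73–76 and matches nothing in
files without segIDs; `range` bounds are inclusive on both ends
(`range: 10-25` selects 16 residues). An expression that matches nothing
returns the empty set, never an error — "hide everything except X" must
not fail on structures lacking X.

## Coloring

Highlight mode is per-atom (a two-color partition by selection); gradient
mode is per-residue (all atoms of a residue share its color), matching
atom-level versus cartoon-level emphasis. Gradient normalization maps
values to t = (v − lo)/(hi − lo) clipped to [0, 1], with lo/hi defaulting
to the observed extremes. Degenerate rules, chosen once and applied to
both colors and radii: unvalued residues get mid-grey (0.5, 0.5, 0.5);
all-identical values with a default range map to the colormap midpoint
(t = 0.5); an explicit lo = hi range over non-constant values is an
error. Colormap stops are equally spaced with piecewise-linear
interpolation — perceptual uniformity is a non-goal.

Built-in per-residue scales: Kyte–Doolittle hydropathy, formal side-chain
charge at pH 7 (Asp/Glu −1, Lys/Arg +1, His 0), and average residue
masses in Da. Residues outside a scale are excluded and reported, not
guessed. Nucleic-acid property tables are an extension point.

## Rendering

The renderer is deliberately minimal so that figures are exactly
reproducible: orthographic projection, consecutive CA–CA segments drawn
as hard (non-anti-aliased) lines, painter's-algorithm ordering by mean
segment depth, white background. Identical inputs give byte-identical
pixel buffers, and every pixel is either background or an assignment
color — properties the test suite asserts literally. Ribbon/cartoon
geometry, lighting and ray tracing are out of scope; "volume" emphasis is
realized by scaling line width with the per-residue radius factor. A
segment takes the color of its first residue; isolated residues render as
dots.

The standard camera aligns the CA principal axes with the image axes
(largest variance horizontal), centers on the CA centroid, and picks the
scale so the worst one-sided projected extent fits inside the margin on
both sides of the frame. The eigenvector sign ambiguity is fixed by
requiring the first CA's projected x and y to be non-negative, and the
depth axis completes a right-handed frame — camera choice is thus a pure
function of the coordinates. Collinear traces fall back to the identity
rotation.

Physical sizing is `px = round(mm / 25.4 × dpi)` throughout.

## Figure layout

A figure plan is a canvas in mm at a target dpi plus ordered panels with
fractional bounds, so one layout serves any dpi. Panels may not overlap
in their interiors (shared edges are fine); labels are lowercase letters,
auto-assigned in insertion order, drawn bold (double-strike of the
embedded bitmap font, which has no bold face) at a 2 mm inset inside each
panel. One "generic" journal preset ships (89 mm single / 183 mm double
column, 247 mm max height, 300 dpi — widths common to the major
life-science journals); presets are a small dataclass users can extend.
Statistical-data panels are accepted only as pre-rendered rasters:
accepting plotting callbacks would make composition non-deterministic.
Vector export is a non-goal.

## Synthetic data

The fixtures module is the package's data source in all tests. It
emulates, at desk scale, the two situations the scoring pipeline exists
for: rigid re-orientation (exact copies under a known rotation +
translation) and conformational noise (i.i.d. Gaussian displacement of
every coordinate). `ideal_helix` builds a CA-only poly-ALA trace on
textbook α-helix geometry (radius 2.3 Å, rise 1.5 Å, twist 100°/residue;
consecutive CA–CA distance √(1.5² + (2·2.3·sin 50°)²) ≈ 3.83 Å).
`perturb` draws from NumPy's PCG64 generator under an explicit seed, so
every decoy is reproducible cross-platform; at σ = 0.5 Å and n = 1000 the
pre-superposition RMSD concentrates near σ√3 ≈ 0.866 Å, which the suite
uses as a calibration check. `apply_rigid` is exact (no coordinate
quantization) so that distance preservation holds to 1e-9; the helix and
perturbation generators quantize to PDB precision so that file round
trips are lossless.

What the generators do **not** emulate: side chains, realistic backbone
covalent geometry under noise, correlated (domain-level) motions,
sequence variation, missing density. Passing tests therefore demonstrate
the correctness of the algorithms on controlled geometry, not robustness
to every artifact of experimental files.

## Problem sizes

The test-suite and acceptance-script computations use 30–100-residue
helices for scoring (1000 residues for the noise-calibration law of large
numbers), 50 random 10-point clouds against a 2°-step exhaustive Euler
grid for Kabsch optimality, and ≤ 1051² px canvases — sizes at which the
exhaustive oracles are themselves cheap to evaluate while every code path
is exercised.

## Known limitations

- GDT/TM report a lower bound on the true maximum over superpositions
  (heuristic search, see above).
- Correspondence is CA-only; nucleic-acid traces (C4′) are an extension
  point, not implemented.
- `by-number` pairing requires the shared residues to appear in the same
  order in both files.
- Atom serial formatting supports the classic 5-column field only
  (≤ 99 999 atoms per model).
- The renderer's painter ordering is per segment, so mutually crossing
  segments at near-equal depth resolve by draw order, not per-pixel depth.
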