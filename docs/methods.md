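# Methods

## Irregular PQS query model

A query is an ordered list of guanine tracts separated by loops of
`loop_min`–`loop_max` (default 1–2) bases drawn from {A, C, T}. Tracts are
open-ended by default (`G{min,}`): a tract consumes a maximal G-run, and a
loop can neither begin nor end inside one because the loop alphabet
excludes G. A family `kG2+mG1` relaxes `m` of the `k+m` tract positions
from `G{2,}` to `G{1,}`; enumerating all placements yields `C(k+m, m)`
queries with zero-padded, lexicographically ordered labels. `N` matches
nothing (neither tract nor loop), keeping "exact match" semantics on
assemblies containing ambiguity codes.

Three overlap policies are provided because they answer different
questions. `all_overlapping` reports every distinct (start, query) match
and is the scientifically complete enumeration; `leftmost_nonoverlap` is
`grep -o` semantics (leftmost, greedy, non-overlapping per query);
`grep_line` reproduces line-oriented `grep` over a wrapped FASTA — at most
one count per file line per query, and matches spanning a line break are
invisible — which is what a genome-wide count obtained with a grep
pipeline actually measures. Scanning defaults to the forward strand;
reverse-complement scanning is available and reports reflected forward
coordinates. Soft-masked (lowercase) bases can be treated as unmatchable
with `--respect-softmask`; by default case is ignored. Strict mode
(`exactly G2 per tract`) compiles closed tracts and forbids a flanking G
on either side of the whole match.

The scanner is validated against a brute-force oracle (recursive
decomposition of every substring, no regular expressions) on the printed
oligos and on hundreds of random strings.

## Topology analysis

**Containers.** Models are lists of residues with PDB-named atoms; residue
numbering follows the input file verbatim. Only residues named DG/G enter
tetrad analysis; modified nucleotides are ignored.

**Glycosidic torsion.** χ is the dihedral O4′–C1′–N9–C4 mapped to
[0, 360). Classes use open intervals: *syn* 0–90°, *anti* 180–240°,
otherwise *undefined* (boundary values are undefined). Across an ensemble
χ is summarized as circular mean ± circular sd.

**Hoogsteen edges.** A directed edge donor→acceptor requires both
heavy-atom distances d(N2_d, N7_a) and d(N1_d, O6_a) within a cutoff of
3.5 Å (default). The cutoff is the restraint target 2.9 Å plus ≈ 2σ of
its 0.3 Å tolerance; heavy atoms are used because deposited models may
lack protons. Each guanine keeps at most one outgoing and one incoming
edge (closest total distance wins). Tetrads are the directed 4-cycles of
this graph whose four bases fit a common plane within 0.75 Å RMSD
(best-fit plane by SVD over base heavy atoms); other cycle lengths and
non-planar cycles are warned about and dropped.

**Stack and polarity.** The stacking axis is the first principal
direction of the tetrad centroids; adjacent layers must be 2.5–5.0 Å
apart (canonical rise ≈ 3.3 Å with margin), otherwise the tetrads form
separate stacks and the error lists the groups. A layer's polarity sign
is the circulation sense of its donor→acceptor cycle viewed along the
axis, computed as sign Σᵢ (vᵢ × vᵢ₊₁)·axis with vᵢ the centroid→N9
vectors in cycle order. Relative polarity between neighbours is `same` or
`reverse`; both are invariant to flipping the stack direction, and a
mirror reflection through a plane containing the axis flips every sign
while preserving the relative pattern.

**Corner columns.** Guanines are grouped into the four corner columns by
projecting base-ring centroids onto the plane perpendicular to the axis
and pairing mutual nearest neighbours between *adjacent* layers (≤ 3.5 Å
projected). Base centroids are used rather than sugar atoms because C1′
swings to opposite edges of a corner when strand directions mix (exactly
what happens in reverse-polarity blocks), and adjacent-layer-only linkage
keeps cumulative helical twist (≈ 30°/layer, i.e. ≈ 90° over four layers)
from bridging distinct corners.

**Loop taxonomy.** Every maximal run of non-tetrad residues (possibly
empty) between sequence-consecutive tetrad guanines of one chain is a
connector. With flanks at layers/columns (l₅, c₅) and (l₃, c₃):

* same layer — `edgewise` if the flanks are cycle-adjacent in the tetrad,
  `diagonal` if opposite;
* same column, adjacent layers — an empty run is an ordinary tract
  continuation (not a loop); a non-empty run is a `bulge`;
* same column, ≥ 2 layers apart — V-shaped;
* adjacent columns, different layers — `propeller` when the destination
  column continues covalently from the 3′ flank toward the source layer
  (the G–G support column exists as part of the 3′ tract), V-shaped when
  that support is absent or non-sequential (the "missing support column");
* anything else — `linker`, with a diagnostic.

V-loops are subtyped by the relative polarity of the two connected
layers: `V_S` (same) or `V_R` (reverse); `span_layers` is the layer
difference plus one. This support-column criterion, rather than a
same-column requirement, is what the published intra-locked structure
actually exhibits: its 2-nt V_S and 0-nt V_R both land on a column whose
supporting guanine is non-sequential, while its four propeller connectors
land on covalently supported columns.

**Intra-lock.** Blocks are maximal runs of adjacent layers without a
polarity reversal. Bridging linkers are connectors — including bulges and
covalent G–G steps — whose flanks lie in different blocks. A structure is
intra-locked when ≥ 2 blocks are fastened by ≥ 2 bridges; a two-block
stack with a single linker is merely stacked, not locked.

**Ensemble RMSD.** For every unordered model pair the selected atoms
(all heavy atoms, or all heavy atoms of the tetrad guanine nucleotides
for the "tetrad core") are superposed by least squares (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`) before computing the
RMSD; mean ± sd over the pairs is reported. The tetrad-core convention
includes sugar atoms of the tetrad guanines; bases-only selection is a
matter of passing the corresponding residue keys.

**Ensemble consensus.** A feature (tetrad composition, loop kind, lock
status) is reported at ensemble level when present in > 50 % of models.

## Restraint generation

Constants are fixed by convention: Hoogsteen H-bond distances H21–N7
2.0 ± 0.2, N2–N7 2.9 ± 0.3, H1–O6 2.0 ± 0.2, N1–O6 2.9 ± 0.3 Å — four per
donor→acceptor pair, sixteen per tetrad; χ dihedrals 240 ± 70° (*anti*)
and 60 ± 70° (*syn*), one per non-excluded guanine; non-exchangeable NOE
classes 2.7 ± 0.8 / 3.8 ± 0.9 / 4.6 ± 1.2 / 5.5 ± 1.7 Å and exchangeable
4.0 ± 1.2 / 4.8 ± 1.4 / 5.5 ± 1.7 Å, with tolerances loosened by 0.5 Å
when thymine methyls are involved. Output is an engine-neutral TSV/JSON
table that round-trips losslessly; an XPLOR-flavoured rendering is
offered for convenience without claiming bit-exactness with any engine
input. Planarity weights (1 kcal mol⁻¹ Å⁻² for tetrads) are recorded as
metadata only; simulated annealing and refinement schedules are out of
scope.

## Melting analysis

The two-state model assigns the folded and unfolded states linear signal
baselines s_F(T), s_U(T); the fraction folded is
θ(T) = (s_U − s)/(s_U − s_F) and Tm is the temperature where θ crosses
0.5. Baselines are initialized on the lowest/highest `baseline_fraction`
(default 0.15) of the temperature span. Because a broad transition's
pure-state tails extend past any end window — a curve with Tm near the
low end of the scan is never fully folded inside the measured range —
window-only baselines are structurally biased (up to ≈ 0.5 °C under this
package's simulation conditions). The implementation therefore refines
the four baseline coefficients jointly with the transition by least
squares on s(T) = θ·s_F + (1−θ)·s_U with van't Hoff θ, and keeps the
θ = 0.5 definition of Tm (for the fitted θ the crossing is the fitted
midpoint). No thermodynamic parameters are reported. Degenerate inputs:
a curve whose baselines coincide raises "no transition in range"; if θ
crosses 0.5 more than once the crossing nearest the steepest slope is
taken with a warning; amplitude below four times the baseline noise marks
the fit unreliable. Heating and cooling branches are fitted
independently; the consensus is (Tm_h + Tm_c)/2 ± |Tm_h − Tm_c|/2, and
ΔTm is the signed difference variant − reference.

Recovery under the simulation conditions used throughout (Tm uniform in
30–70 °C, folding ΔH −45 kcal/mol, 15–90 °C scan at 0.5 °C steps, noise
0.5–2 % of amplitude): median |T̂m − Tm| ≈ 0.1 °C.

## Synthetic fixtures

**Planted FASTA.** Background is drawn uniformly from {A, C, T}, so no
accidental G-tract can occur and the truth BED is exhaustive by
construction; planted instances are non-overlapping with a minimum gap.
Everything is deterministic given the seed.

**Idealized G4 coordinates.** Guanine bases use standard base-frame
dimensions. A reference in-plane placement (rotation + translation) is
solved once by least squares so that four copies related by 90° rotations
form a planar Hoogsteen quartet with N2–N7 and N1–O6 within 10⁻⁴ Å of
2.9 Å, carbonyl O6 ring near the axis and C1′ corners at a realistic
radius. Layers stack at rise 3.3 Å and twist 30°/layer; reverse-polarity
layers are built turned over (a proper rotation), which reverses their
circulation along the common axis. Sugar O4′ atoms are placed by
internal-coordinate construction to realize each residue's planned χ
exactly; loop thymines are placed as non-clashing exterior spacers (the
generator rejects any non-bonded contact under 1.5 Å). Strand plans are
validated to fill every (layer, corner) slot exactly once. Additional
models are rigid random reorientations with optional per-coordinate
Gaussian jitter. The randomized-recovery battery uses jitter 0.08 Å: the
detection margin between the 2.9 Å bond and the 3.5 Å cutoff is then
≈ 5σ of the induced distance noise, so exact recovery is the expected
outcome and any failure is a genuine defect; larger jitter makes the
cutoff itself a coin-flip, which tests statistics rather than code.

These fixtures are analyzer-grade idealizations, not force-field
structures: backbone atoms beyond C1′/O4′ are absent, loop geometry is
schematic, and bond lengths are not contractual — only the
analyzer-facing criteria (H-bond distances, planarity, stacking
geometry, χ) are. Passing on them demonstrates the analyzer's logic, not
robustness to experimental coordinate error beyond the jitter tested.

**Melting curves.** θ(T) = 1/(1 + exp((ΔH/R)(1/T − 1/Tm))) with absolute
temperatures and folding ΔH < 0; the signal interpolates between the two
baselines with additive Gaussian noise. Default ΔH −45 kcal/mol — a
realistic folding enthalpy for a four-layer G4 and deliberately broad, so
the baseline problem above is exercised rather than hidden.

## Known limitations

* Loop classification assumes a single contiguous stack of ≥ 2 tetrads;
  separated stacks are reported as an error listing the groups rather
  than analyzed per block.
* Left/right handedness is not called; polarity signs are relative.
* The propeller/V discrimination relies on residue numbering being
  sequential along the chain (true for deposited and generated
  structures).
* grep_line counts depend on the FASTA's line wrapping, by design — they
  replicate a line-oriented pipeline, not the biological match count.
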