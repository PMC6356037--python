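# Methods

## Motif model

A heme-binding motif (HBM) is modeled as a window of up to nine residues
centered on an axial ligand P⁰ ∈ {C, H, Y}: four flanking residues on each
side, truncated at the sequence termini. Truncated windows are reported
with explicit `left_truncated`/`right_truncated` flags rather than dropped:
nothing establishes that a site within four residues of a terminus is
invalid, and silently dropping terminal sites would hide candidates. The
scanner reports every C/H/Y independently; overlapping windows from
adjacent sites are not merged, so the number of windows always equals the
number of C/H/Y residues. Selenocysteine (`U`) is not treated as a
coordination site; methionine and lysine — occasionally observed as
ligands — can be enabled via the `ligands` configuration key (default
`CHY`).

**Net charge** is the integer count (#K + #R) − (#D + #E) over the window.
Histidine is neutral at the implied physiological pH (a
`histidine_positive` toggle counts it +1 for acidic conditions), and no
terminal charges are added because the window is an internal protein
fragment. This is the simplest reproducible convention consistent with the
qualitative observations it annotates (negative charge disfavors, positive
favors heme binding); no formula beyond "net charge" is established, so the
convention is a package decision.

**CP detection** requires the axial cysteine to be immediately followed by
proline inside the window; a terminal cysteine with no +1 residue is not a
CP motif.

**Ancillary sites** are further C/H/Y residues at window offsets −4…+4
(≠ 0). Coordination partners farther away are out of scope — the class
system is defined on the 9-mer. Windows with several ancillary residues are
treated the same as windows with one (the criterion is binary ≥ 1).

## Classification

The eight classes partition (ligand C/H/Y) × (±ancillary), with the
cysteine branch split by CP: 2 (C/CP) × 2 + 2 + 2 + 2 = 8. CP status
dominates the cysteine split, so a CP window with an ancillary site is
class IV, never II. The coordination/topology metadata attached per class
(penta = {III, IV, V, VII}, hexa = {I, II, VI, VIII}; sandwich-like for I
and VIII, loop/clamp-like for II and VI) summarizes peptide-level
spectroscopy and NMR and is emitted as a hint in the report's comment
column, never as a prediction for the protein at hand. The numbering of
the histidine/tyrosine classes (V/VI, VII/VIII as no-ancillary/ancillary)
is an interpretation consistent with the penta/hexa grouping; the class
table is exportable (`hemescan classes`) so users who number the classes
differently can re-map, and the `class_overrides` configuration key can
adjust the coordination/topology metadata without code changes.

## Exposure filtering

Default mode keeps only coordination sites labeled exposed; structure mode
is the identity (the user curates against known structure). Unknown labels
pass the default-mode filter with a logged warning — missing evidence
should not suppress a candidate. Profiles come from:

* the built-in heuristic: sliding-window (default 9, odd) mean
  Kyte–Doolittle hydropathy, label buried where the mean exceeds 0.0
  (GRAVY sign convention: positive = hydrophobic core). The window mean is
  computed with `math.fsum` so the labels are exactly invariant under
  sequence reversal. Residues without a hydropathy value (X, B, Z, U, O, J)
  contribute 0 with a warning. This heuristic stands behind the same
  interface as file import, so labels from a dedicated solvent-accessibility
  predictor can be plugged in without code changes — which is what a
  careful user should do, since a hydropathy mean is a crude proxy for
  burial;
* a two-column file (1-based position, `exposed`/`buried` or an RSA
  fraction in [0, 1] binarized at a cutoff, default 0.25, the common
  surface/buried convention). Unlisted positions become `unknown`.

## Pattern matching

The PROSITE dialect is parsed into element lists (fixed residue,
alternative set `[..]`, exclusion set `{..}`, wildcard `x`, with repeats
`(n)` and ranges `(n,m)`; `<`/`>` anchors; terminal `.` ignored). Matching
reports every start position with a match; for ranged repeats the
*shortest* match at each start is reported, computed as a reachable-end-set
dynamic program over element index × sequence position (deterministic by
construction, not dependent on backtracking order). An `X` in the sequence
satisfies only wildcards — an unknown residue is never allowed to satisfy
a specific requirement, including exclusion sets (the unknown residue
might be the excluded one). Matching is case-insensitive. The property
suite checks the matcher against an independent brute-force enumeration
oracle on random sequence/pattern pairs.

## Spectroscopic rule engine

Band positions (already-extracted maxima; no peak picking) map to
coordination verdicts:

| technique | rule | verdict |
|---|---|---|
| UV/Vis | lone Soret maximum within ±8 nm of 370 nm | penta |
| UV/Vis | lone maximum in 415–435 nm | ambiguous (not uniquely assignable) |
| UV/Vis | maxima in both bands | mixed |
| rRaman | lone ν₃ within ±5 cm⁻¹ of 1491 cm⁻¹ | penta (caveat: free hemin identical) |
| rRaman | lone ν₃ within ±5 cm⁻¹ of 1505 cm⁻¹ | hexa |
| rRaman | double band | mixed |
| cw-EPR | g within 6 ± 0.4 **and** g within 2 ± 0.4 | penta (high spin) |
| cw-EPR | exactly three g-values all in 1.5–3 | hexa (low spin) |

All band centers and tolerances are configurable (`Tolerances`); the
defaults quantify the "approximately" with which band positions are
reported. Widening a tolerance can only convert undetermined → matched,
never flip penta ↔ hexa (tested as a property). ν₇ positions are accepted
but recorded as uninterpreted — no quantitative ν₇ rule is established.

The combiner passes unanimous verdicts through, lets any decisive technique
resolve an ambiguous UV call, turns any mixed partial — or a direct
penta-vs-hexa conflict between techniques (flagged in the evidence) — into
`mixed`, and returns `undetermined` exactly when no technique matched any
rule. Within a single EPR readout of ≤ 3 g-values the high-spin and
low-spin patterns cannot co-occur, so EPR-internal `mixed` is unreachable;
mixtures surface through the combiner instead. UV spectra are additionally
labeled with groups I–IV (370-only, 420–430-only, both, neither); the
groups are named but not formally defined in the source literature, so this
mapping is an explicit interpretation and is labeled as such.

## Synthetic library generator

The generator emulates the combinatorial X₄(C/H/Y)⁰X₄ one-bead-one-compound
nonapeptide library: a center drawn from {C, H, Y} and eight i.i.d. flank
residues from a 19-letter alphabet (20 standard minus Cys, to avoid
intramolecular disulfides, and Met, incompatible with the sequencing
chemistry, plus norleucine written `J`). Defaults:

* `center_weights = {H: 0.40, Y: 0.40, C: 0.20}` — the axial-ligand
  frequencies observed among heme-*binding* hits. The synthesized library
  itself is uniform over {C, H, Y}; both regimes are exposed
  (`--uniform-centers` on the CLI) and the distinction matters when
  interpreting calibration numbers.
* uniform flank sampling. An optional polar-enrichment weight (> 1
  up-weights E, D, Q, N, R, K, H, Y, mirroring the polar skew of binder
  flanks) is off by default because no numeric enrichment is established.

Under uniform flanks the probability that a peptide carries ≥ 1 ancillary
His/Tyr is 1 − (17/19)⁸ ≈ 0.589 in closed form, consistent with the "> 50%
of hits" observation; the Monte-Carlo estimate is checked against the
closed form within three binomial standard errors at n = 10,000, a sample
size at which those checks resolve the 20% / 58.9% rates to about ±1
percentage point while running in well under a second.

Sampling uses `numpy.random.Generator` (PCG64), fully determined by the
seed; flank draws are plain integer indices into the alphabet. Only
sequences are simulated — bead chemistry, heme incubation concentrations
and binding outcomes have no computable model here — so passing calibration
tests demonstrates that the generator reproduces its design frequencies,
not that the scanner would perform equivalently on real proteomes (real
proteins have non-uniform composition, domain structure and genuine
exposure patterns the simulator does not emulate).

## Pipeline and I/O

`scan` runs FASTA → site finding → exposure filtering → window extraction →
classification → annotated TSV, logging per-stage counts to stderr. The
report is byte-deterministic for identical inputs and configuration. FASTA
parsing accepts lowercase (uppercased) and strips `*` stop characters with
a warning; any character outside the 20 standard codes plus X/B/Z/U/O/J is
rejected with record, position and character named. A user-supplied
accessibility file applies only to single-record FASTA input (the
two-column format carries no record identifier). Exit codes: 0 success,
2 usage, 3 validation/config, 4 I/O.

## Known limitations

* The built-in exposure heuristic is a hydropathy proxy, not a trained
  solvent-accessibility predictor; its labels should be treated as a first
  pass.
* Binding affinity is not predicted; net-charge comments are qualitative.
* The eight-class metadata derives from nonapeptide model systems;
  transfer to full-length proteins is a hypothesis the report's wording
  deliberately hedges.
* The pattern matcher implements patterns only, not PROSITE profile
  matrices.
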