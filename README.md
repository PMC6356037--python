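# hemescan

Sequence-based detection and classification of transient heme-binding
motifs (HBMs) in proteins.

Labile (regulatory) heme binds proteins through short, surface-exposed
motifs coordinating the ferric iron via a cysteine, histidine or tyrosine
side chain — the axial ligand at position P⁰ of the 9-mer nomenclature
X₄(C/H/Y)⁰X₄. `hemescan` is for biochemists who have a protein sequence and
want a shortlist of candidate coordination sites with the sequence features
that matter for heme binding: the 9-mer motif window, its integer net charge
(#K + #R − #D − #E; a negative charge disfavors binding, a positive one
favors it), whether the axial ligand starts a cysteine–proline (CP)
dipeptide, and any additional potential coordination sites within the
window.

Each motif is assigned to one of eight HBM classes partitioning
(axial ligand) × (CP for Cys) × (±ancillary site):

| class | definition        | expected coordination | topology        |
|-------|-------------------|-----------------------|-----------------|
| I     | C, no CP          | hexa                  | sandwich-like   |
| II    | C + ancillary     | hexa                  | loop/clamp-like |
| III   | CP                | penta                 | single          |
| IV    | CP + ancillary    | penta                 | single          |
| V     | H                 | penta                 | single          |
| VI    | H + ancillary     | hexa                  | loop/clamp-like |
| VII   | Y                 | penta                 | single          |
| VIII  | Y + ancillary     | hexa                  | sandwich-like   |

The coordination/topology columns are peptide-level spectroscopic and NMR
evidence attached as hints, not structure predictions.

The package also provides:

* **exposure filtering** — the scanner's default mode drops coordination
  sites predicted to be buried (a built-in Kyte–Doolittle hydropathy
  heuristic, or user-supplied per-residue exposed/buried or RSA labels);
  structure mode reports every site for manual curation;
* **PROSITE-syntax pattern matching** — screen consensus motifs such as
  `H-x(3)-C` (the loop-forming HXXXC arrangement) locally against FASTA
  databases;
* **a spectroscopic rule engine** — maps UV/Vis Soret maxima (∼370 nm
  penta; ∼420–430 nm not uniquely assignable), resonance-Raman ν₃ bands
  (∼1491 cm⁻¹ penta / free hemin, ∼1505 cm⁻¹ hexa, double band mixture) and
  cw-EPR g-values (g ≈ 6 with g ≈ 2 high-spin penta; three g-values in
  1.5–3 low-spin hexa) to coordination-state calls with an evidence trail;
* **a synthetic library generator** — seeded simulation of the
  combinatorial X₄(C/H/Y)⁰X₄ nonapeptide library (19-letter flank alphabet
  excluding Cys/Met, including norleucine `J`) used for fixtures and
  calibration checks.

## Worked example

Scan a peptide realizing the HXXXC arrangement:

```sh
printf '>p1 test\nHAAACAAAA\n' > t.fa
hemescan scan -f t.fa --mode structure
```

```text
record_id	position	axial_ligand	motif	net_charge	class	exposure	comment
p1	1	H	HAAAC	0	VI	unknown	additional coordination site(s): C at +4; class VI: expected hexa-coordination, loop/clamp-like complex (peptide-level evidence)
p1	5	C	HAAACAAAA	0	II	unknown	additional coordination site(s): H at -4; class II: expected hexa-coordination, loop/clamp-like complex (peptide-level evidence)
```

Both coordination sites are reported (structure mode does no exposure
filtering). The cysteine at position 5 carries the distal histidine at
offset −4 — three residues of spacer, the geometry that allows a
loop/clamp-like hexa-coordinated complex — so it is class II with net
charge 0. The truncated window at position 1 is the same pair seen from the
histidine's side (class VI).

Interpret a spectroscopic readout:

```sh
hemescan spectro --soret 370 --nu3 1491
```

```text
id	verdict	uv_group	evidence
sample	penta	I	UV/Vis: lone Soret maximum near 370.0 nm; rRaman: nu3 band near 1491 cm-1 (caveat: indistinguishable from free hemin)
```

Other subcommands: `hemescan patterns --pattern "H-x(3)-C" -f db.fa`,
`hemescan simulate --n 1000 --seed 42`, `hemescan classes`.

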