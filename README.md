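# prolamap

Curation, classification, coeliac-toxic-motif mapping and chymotryptic
marker-peptide analysis for cereal prolamin (gluten) protein sequence
databases.

## The problem

Mass-spectrometric quantitation of gluten in food needs curated protein
sequence databases: raw UniProt/NCBI downloads of prolamin seed storage
proteins (gliadins in wheat, hordeins in barley, secalins in rye,
avenins in oats) are dominated by duplicate deposits, partial sequences
and records with ambiguous residues. Once curated, the sequences are
classified into protein groups (α-, γ-, δ-, ω-type prolamins, LMW/HMW
glutenin subunits, avenins and avenin-like proteins), screened for
coeliac-toxic T-cell epitope motifs, and digested in silico to find
proteotypic marker peptides for targeted methods.

`prolamap` implements that workflow as a deterministic, testable
pipeline, plus a synthetic prolamin-family generator with exact ground
truth so every stage can be verified without any external downloads.

## What it computes

* **Curation** — exact-duplicate collapse with UniProt accessions
  preferentially retained, removal of records with ambiguity letters
  (X/B/Z/J) and of likely partials (length floor, missing initiator
  Met, "(Fragment)"-style keywords), and a proline+glutamine screen
  (P+Q ≤ 30% is flagged, not removed). Every removal is logged with one
  reason so that *n*ᵢₙ = *n*ₖₑₚₜ + removals.
* **Classification** — global Needleman–Wunsch identity (BLOSUM62, gap
  open 10 / extend 0.5; identity = matches / alignment columns, gaps
  included) against per-group master sequences, with cysteine-skeleton
  counts (8 C in the prolamin superfamily core, 9 in A-avenins, 0 in
  ω-types) and repeat grammars (e.g. `PFM` Q₁₋₅, `MLL` Q₃₋₆, `PFV`
  Q₂₋₄, literals `VFQPQLQQ`/`FFQPQMQQ`/`VTQG`) as evidence and
  tie-breakers.
* **Phylogeny** — average-distance (UPGMA) trees over d = 100 − %id,
  cut into clusters that recover the protein groups.
* **Motif mapping** — for a panel of coeliac-toxic peptides matched as
  exact substrings: per sequence, the number of distinct motifs present
  *m*, the density *m/L*, and the percent of residues covered by the
  union of all motif hit intervals.
* **Marker discovery** — chymotryptic digestion (cleave after Y/W/F/L
  unless followed by P, ≤ 2 missed cleavages), monoisotopic masses
  (optional fixed carbamidomethyl-C), database-relative peptide
  uniqueness (optional I=L), and marker filters: unique, ≥ 5 residues,
  ≥ 750 Da.

## Worked example

```python
>>> from prolamap import MotifPanel, motif_metrics
>>> panel = MotifPanel(["PFPQ", "QQPFPQ", "QQQQ"])   # PFPQ is a fragment of QQPFPQ
>>> mm = motif_metrics("QQPFPQQPQQPFPQ", panel)
>>> mm.unique_count, round(mm.density, 4), mm.coverage_percent
(2, 0.1429, 85.71)
```

Two distinct motifs match (`QQPFPQ` at 1–6 and 9–14, its fragment
`PFPQ` nested inside both), giving m = 2, density 2/14 ≈ 0.1429 motifs
per residue, and 12 of 14 residues (85.71%) under the hit-interval
union — residues 7–8 are uncovered.

The full pipeline runs from a shell. On the bundled synthetic fixture
(6 groups, 30 clean records plus 3 duplicate, 2 ambiguous and 2 partial
corrupted records):

```sh
$ prolamap simulate --seed 1 --out-dir fx
37 records -> fx/sequences.fasta
$ prolamap curate fx/sequences.fasta --out curated.fasta --report report.tsv
kept 30/37; removed {'duplicate_sequence': 3, 'ambiguous_residue': 2, 'partial_sequence': 2}
$ prolamap tree curated.fasta --out tree.nwk --cut 30 --groups-out groups.tsv
tree over 30 leaves written to tree.nwk
```

Curation removes exactly the seven injected corrupted records, and
cutting the UPGMA tree at identity-distance 30 yields six clusters —
one per planted prolamin group.

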