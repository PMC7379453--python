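# Methods

## Curation model

Curation is a deterministic re-statement of the manual clean-up applied
when building curated prolamin databases. Rules run in a fixed order —
duplicate collapse, then ambiguity removal, then partial removal — so
that the *retained* representative of a duplicate group, not a
discarded copy, is the record that gets content-checked. Each removed
record carries exactly one (first-triggered) reason, which makes the
report conservative: `n_input == n_kept + len(removals)` always.

* **Duplicates.** Records sharing an accession keep the first
  occurrence. Exact duplicate sequences (string equality) keep one
  representative chosen by source preference
  (`uniprot_sp > uniprot_tr > ncbi > other`), ties broken by input
  order. With a fully resolving preference, the *set* of kept sequences
  is invariant under input permutation (property-tested).
* **Ambiguity.** Any of X/B/Z/J removes the record. These letters are
  *readable* on input (the curation stage has to be able to see them);
  U, O and stop characters are hard read errors.
* **Partials.** No public rule distinguishes a partial from a
  short-but-complete sequence, so "partial" is operationalised by three
  explicit, configurable signals: length < 50 residues (well below any
  mature avenin, purely a fragment guard), a missing initiator
  methionine when no signal peptide is annotated, and header keywords
  (`partial`, `fragment`, `(Fragment)`, case-insensitive).
* **Composition.** P+Q content = 100·(#P + #Q)/L, reported to two
  decimals. Sequences at or below the 30% prolamin-confirmation
  threshold are flagged, never removed: genuine prolamins (avenins,
  some avenin-like proteins) sit in the 22–35% range, so removal would
  discard true positives.

## Alignment and identity

All identities are global (end-to-end) pairwise alignments with
BLOSUM62 and affine gaps, open 10 / extend 0.5 — BLOSUM62 because it is
the standard matrix for this family of analyses, the gap costs a widely
used global-alignment default; both are configurable. Identity is
100 × identical aligned pairs / alignment columns, with gap columns in
the denominator. This is one of several identity conventions, so
published within-group similarity figures computed with unknown tools
should be compared only approximately. The sequence pair is canonically
ordered before aligning, which makes the reported identity symmetric
even when several alignments are co-optimal (the aligner then picks its
first optimum deterministically).

Classification is master-identity-driven: the record takes the group of
its best-identity master when identity ≥ 30% (the homology floor used
to recover candidate prolamins during database construction); repeat
hits and template order only break exact identity ties. Cysteine counts
and repeat-grammar hits are reported as evidence rather than used as
hard rules, because real group assignment mixes phylogeny with
literature knowledge that no fixed rule captures. Repeat grammars match
a literal prefix followed by a greedy glutamine run capped at the
pattern maximum; overlapping occurrences are all reported, since no
canonical occurrence semantics exists for these repeats.

## Trees

UPGMA (size-weighted average linkage) over identity distance
d = 100 − %id: merge the closest pair at height d_min/2, update
distances by size-weighted means, break ties by the smallest
(row, column) index pair in current label order — ties are common with
repetitive sequences, so the tie rule is part of the contract. The
output is rooted, binary and ultrametric (three-point condition to
1e-9; cophenetic distance = 2 × merge height). UPGMA is used, not
neighbour joining, because the clustering assumes an equal rate of
evolution and is read only for group membership; branch lengths are in
identity-percent units, not substitutions per site, and no branch-length
agreement with published figures is claimed. Tests cross-check against
SciPy's average-linkage cophenetic matrix as an independent oracle.

## Motif statistics

Motifs match as exact, case-sensitive substrings, overlapping
occurrences and nested fragments included. Per sequence: m = number of
distinct panel motifs with ≥ 1 hit (repeat occurrences of one motif do
not increase m; a fragment and its parent motif count separately);
density = m/L per residue (a per-100-residue column is emitted
alongside); coverage = 100 × |union of hit intervals| / L to two
decimals. Duplicate motifs in an input panel are collapsed with a
warning so m is well-defined. Matching is on the sequence as given —
deamidation-aware (Q→E) variants are out of scope, and whether to
analyse mature or immature (signal-containing) sequences is the
caller's choice via `signal_len` (default: the sequence as given).
Group summaries use linearly interpolated quartiles (NumPy default).

## Digestion and markers

Chymotrypsin cleaves after Y, W, F or L when a following residue exists
and is not P. Zero-missed peptides tile the parent exactly; j-missed
peptides concatenate j+1 consecutive fragments (j ≤ 2 by default), so
with s internal sites the peptide count is Σ_{j=0..min(k,s)} (s+1−j) —
verified against brute-force enumeration. Monoisotopic masses are
residue sums plus water (via pyteomics), with fixed
carbamidomethyl-C (+57.021464 Da) as the only supported modification;
variable modifications are out of scope. Uniqueness is database-relative
on the peptide string; I/L merging is off by default (MS cannot
distinguish them — flag `--ileq`) and never increases the number of
unique peptides. Marker filters: unique, ≥ 5 residues, ≥ 750 Da. The
750 Da precursor cut-off is applied to the neutral monoisotopic peptide
mass — a documented approximation, since charge states are outside this
MS-free scope. Protein C-termini always end a peptide; N-terminal Met
receives no special processing.

## Synthetic generator

Each group template is signal peptide (20 aa, starts with M, no C or
Y/W/F/L) + N-terminal domain (30 aa) + 3–9 copies of a group repeat
unit (a realisation of the group's repeat grammar plus a 5-aa spacer) +
C-terminal domain (60 aa) carrying the fixed cysteine skeleton (8 or 9
C; 0 for the ω-like group; 4 for the HMW-like group, whose long repeat
domain disrupts the skeleton). The residue background is 35% Q / 15% P
over the standard alphabet minus C, mimicking prolamin composition and
guaranteeing that the cysteine count equals the skeleton size.

Motif panels are generated from the same Q/P-rich background (default
25 motifs of 6–10 residues, 20% of them fragments of other motifs).
1–3 distinct motifs are spliced into each record's repeat region at
recorded, non-overlapping coordinates. Point mutations (default rate 0)
are i.i.d. substitutions that never touch the initiator Met, embedded
motif spans or cysteines — so ground truth stays exact — while expected
motif metrics are computed *after* assembly by an independent
per-residue brute-force oracle, so incidental matches created by the
repetitive background are counted, exactly as a real mapping would.
Corrupted records (3 NCBI-sourced exact duplicates, 2 records with an
injected X, 2 truncated "(Fragment)" records at staggered lengths, so
same-group truncations cannot collide as duplicates) exercise every
curation rule.

The default fixture ("toy-glupro", seed 1) is 6 groups × 30 clean
records. Sizes were chosen so the full pipeline — including the
all-against-all alignment for the tree — completes in about a second
while every group still contains enough members for within-group
statistics. What passing tests on this fixture show: the *rules* are
implemented correctly and recover planted structure exactly at zero
mutation. What they do not show: that the heuristics (partial
detection, identity floor, identity convention) reproduce any
particular published database built from real downloads, where
divergence is evolutionary rather than i.i.d. and annotation quality
varies.

## Numerical choices

* Percentages (identity, coverage, P+Q) are rounded to 2 decimals at
  the reporting boundary; densities kept at full precision with a
  rounded per-100 convenience column.
* UPGMA comparisons use a 1e-15 strict-improvement guard so exactly
  equal distances fall to the index tie-break.
* FASTA round-trip is exact: headers are rebuilt in the record's own
  dialect (`sp|ACC|ACC`, `tr|ACC|ACC`, plain token) and the `OS=`
  species field is stripped into the species attribute on read and
  re-appended on write. `signal_len` is not serialized (FASTA carries
  no such annotation).
* Exit codes of the CLI: 0 success, 2 configuration error, 3 data
  error.

## Known limitations

No homology-based (BLAST) screening of non-prolamins, no multiple
alignment, no signal-peptide prediction, no spectral search, FDR or
ppm-tolerance modelling, and no live retrieval from UniProt/NCBI — the
library never touches the network. Published headline numbers that
depend on downloaded sequence sets or raw MS data are therefore outside
what this package can recompute; the acceptance script reports the
quantities the package itself computes on generated inputs.
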