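# Methods

This note documents the models and procedures behind codoncraft, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Codon-usage tables and CAI

A usage table is estimated by counting codons over a reference CDS set and
normalizing within each synonymous family: frequency `f_c = n_c / Σ_family n`,
relative adaptiveness `w_c = f_c / max(f_family)`. The reference set is
meant to be the coding sequences of the host's most highly expressed genes;
`rank_top_genes` takes an (id, expression) table, sorts by descending value
with lexicographic id tie-break, and returns exactly *n* ids — a tie at the
rank boundary is cut, not included, so output size is deterministic.
Expression values are used as given (any monotone unit works; no
re-quantification is attempted).

Conventions and edge cases:

- The genetic code is the standard nuclear code (NCBI table 1), which the
  intended host (*Y. lipolytica*) uses. Stop codons are counted and carry
  family frequencies/weights like any other family, but are never CAI
  terms and are only exchanged stop-for-stop during repair.
- A family never observed in the reference set gets uniform frequency and
  uniform weight `1/|family|` and is flagged `unobserved` — a deliberate
  departure from `w = f/f_max` so that CAI never takes `log 0`.
- A codon observed zero times in an otherwise observed family gets the
  conventional floor weight 0.01 (the EMBOSS `cai` convention), keeping
  weights in (0, 1] while still penalizing rare codons heavily.
- CAI is the geometric mean of weights, computed in the log domain,
  excluding stop codons and the single-codon families Met and Trp. A
  sequence with no includable codon has no CAI; scoring raises, and the
  optimizer records `None`.
- An internal stop codon in a reference CDS is recorded in the table's
  provenance notes and counting continues (truncated or mis-annotated
  CDSs should be visible, not fatal).

The serialized format is one TSV row per 64 codons
(`codon, amino_acid, count, freq, weight`, 6-decimal reals) with
`#`-prefixed provenance; the reader re-validates completeness and
per-family normalization, so a corrupted table fails loudly.

## Strict back-translation and constraint repair

Back-translation assigns each residue its family-maximal-weight codon
(ties: lexicographically smallest codon text) and appends the
highest-count stop codon. By construction the strict encoding has CAI 1
against its own table.

The constraint model:

| constraint | default | unit / meaning |
|---|---|---|
| forbidden motifs | BsaI `GGTCTC`, EcoRI `GAATTC`, BamHI `GGATCC`, NotI `GCGGCCGC` | IUPAC DNA, matched on both strands |
| max homopolymer | 8 | longest allowed single-base run, nt |
| GC window | 50 nt, 30–65 % | sliding window, 1-nt step |
| global GC | off | optional (min, max) |

Motifs are checked on both strands because restriction enzymes act on
double-stranded DNA; NotI is in the default set because optimized inserts
are destined for NotI-digested vectors. Violation coordinates are 0-based
half-open nucleotide intervals; each violating GC window is reported
individually (reports are exhaustive, not merged).

Repair is deterministic and greedy-with-backtracking. Starting from the
strict encoding:

1. Scan; take the leftmost violation `v`.
2. Enumerate synonymous single-codon substitutions at codon positions
   overlapping `v`, ordered by smallest weight loss, then leftmost
   position, then codon text. Accept the first whose result (a) no longer
   contains `v` and (b) contains no violation ending strictly before
   `v.end`. A new violation ending at the same coordinate is tolerated:
   repairing a long homopolymer run necessarily proceeds through residual
   runs sharing the run's right edge, and the left-to-right sweep still
   makes progress.
3. If no single substitution is acceptable, search substitution chains
   depth-first up to `backtrack_depth` (default 3) in the same candidate
   order, with a global node budget.
4. Re-scan and repeat; an iteration cap (4·length + 100) guards
   termination, after which the residual report is raised as
   constraint-infeasible.

Only synonymous substitutions are ever made (the terminal stop may swap to
another stop), so translation preservation is structural, and it is also
asserted at the end of every run. The small-instance optimality property —
for short proteins with one forbidden motif the result attains the maximum
CAI over all compliant encodings — holds because candidates are tried in
weight-loss order and a single motif occurrence destroyed by a multi-codon
change is always destroyed by one of its component changes; the test suite
verifies it against exhaustive enumeration rather than taking the argument
on faith.

Known limitation: with depth 3 the repair cannot lift a 50-nt window that
needs more than ~3 GC-increasing substitutions (e.g. a long lysine-rich
stretch under a low-GC table), and some compositions (poly-Trp, poly-Pro,
poly-Gly) have no synonymous encoding inside a 30–65 % window at all. Such
inputs raise constraint-infeasible with the residual report; raising
`backtrack_depth` or relaxing the window is the caller's decision. No
mRNA-structure, codon-pair or harmonization objectives are modeled.

## Construct engineering

- `truncate_n` deletes a 1-based inclusive residue range; with
  `keep_initial_met` a deletion starting at residue 1 starts at 2 instead
  (the Δ2-37-style form). Deleting through the C-terminus is refused. The
  output id carries the effective `Δfrom-to` suffix.
- `fuse` joins two proteins through `linker_motif × repeats` (default GSG
  × 1; 0 gives a direct fusion; 4 is a commonly useful longer linker). The
  upstream stop symbol is removed once per junction, which is exactly what
  makes fusion associative for a fixed linker. The downstream partner is
  used verbatim — whether it retains an initial Met is the caller's
  decision.
- `swap_ntm` builds chimeric CDSs: donor codons `1..d` + recipient codons
  `r+1..end`, where `d` and `r` are the last residues of the respective
  N-terminal transmembrane domains (supplied as inputs; domain prediction
  is out of scope). The splice maps residue `r` to nucleotide `3r`, so the
  frame is preserved arithmetically and no junction re-optimization is
  performed. A junction that would create an internal stop not present in
  either input raises.

## Global alignment

Gotoh's three-state affine-gap dynamic program, global mode, with a gap of
length L costing `gap_open + (L−1)·gap_extend` and needle's DNA defaults
(+5/−4, 10, 0.5). End gaps are penalized like internal gaps. Traceback is
deterministic: ties resolve diagonal > up > left, both between states and
within a state's predecessors, so two runs are byte-identical. Percent
identity is `100 · matches / alignment_length` with gap columns in the
denominator (needle's report convention). The identity matrix computes
each unordered pair once and mirrors it; values are full precision
internally and rounded to one decimal only for display.

The implementation is pure Python and comfortable up to a few kilobases
per pair; the test oracle is an independent memoized recursion over edit
operations (itself validated against full enumeration on very short
pairs), plus the closed-form check that with match 1 and all other costs 0
the optimum equals the LCS length, and a cross-check against Biopython's
`PairwiseAligner` under identical scoring.

## Synthetic fixtures

`generate_cds_set` draws proteins residue-by-residue (uniform amino-acid
composition unless a vector is given) and codons from stated per-family
frequency vectors; every CDS starts ATG, ends with a sampled stop, and has
no internal stop. The default `skewed_bias(decay=0.35)` gives codon *i* of
each family (lexicographic order) probability ∝ 0.35^i — a sharp skew of
the kind seen in highly expressed genes. All randomness flows through one
seeded numpy Generator, so identical specs give byte-identical FASTA.

What this emulates: a reference set with strong, known codon bias, which
lets table estimation be checked as a parameter-recovery problem (200
genes × 300 codons recover per-family frequencies within ±0.03, consistent
with the 3·√(p(1−p)/n) binomial bound at ~3000 draws per family). What it
does not emulate: real length/composition distributions, GC gradients,
dinucleotide structure, or any organism's actual genome statistics.
Passing tests therefore establish the algorithms' correctness contracts,
not biological performance of designed sequences.

`generate_violating_sequence` embeds exactly one violation class (a
motif, an over-cap homopolymer run of exact requested length, or an
AT-rich stretch spanning a GC window) in neutral ~50 %-GC filler codons,
and verifies the claim internally with `scan_violations` before returning;
impossible requests (run shorter than the cap) are rejected.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 200 random proteins ≤ 7
residues for exhaustive-optimality, 1000 random proteins (5–50 residues)
for translation/compliance, 500 random pairs ≤ 8 nt for alignment-oracle
equivalence, 200 × 300-codon CDSs for frequency recovery, a 300-residue
query for end-to-end optimization, and a 200-codon gene for the
native-vs-optimized identity comparison. These sizes make the whole suite
run in seconds while keeping every estimate's sampling error well inside
the asserted tolerances.
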