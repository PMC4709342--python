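# Methods

This note records the models, conventions and numerical choices behind
`cysanchor`, in the order the pipeline uses them.

## Barcode design

A barcode is a length-`L` peptide over a small alphabet of rare residues
(default `L = 10` over {W, H, M, Y}, the four least common amino acids in
average protein composition). Three statistics govern the set:

* **Composition Shannon entropy** `H = -Σ_a p_a log2 p_a` over the
  barcode's residue frequencies, in bits. Threshold `entropy_min = 1.8`
  bits (max over a 4-letter alphabet is 2.0). With `L = 10` this admits
  exactly the compositions {3,3,2,2}, {4,2,2,2}, {4,3,2,1} and {3,3,3,1}
  — every admitted barcode uses all four letters.
* **Hamming+ distance**: unit-cost edit distance (substitutions plus
  indels), threshold `distance_min = 4` pairwise across the set. Edit
  distance rather than substitution-only Hamming matters because an
  aligner can shift a barcode: two barcodes 4 edits apart cannot be
  confused by a single indel plus a couple of substitutions. Computed
  with edlib (banded, `k = distance_min - 1` during generation) and a
  pure dynamic-programming fallback.
* **Chance-match probability**: for a barcode `b`,
  `P(window) = Π_i f(b_i)` under background amino-acid frequencies
  (bundled average-composition table, user-overridable), and
  `P(match) = P(window) × n_windows` with
  `n_windows = n_sequences × (sequence_length − L + 1)`, floored at zero.
  For the default alphabet every 10-mer satisfies
  `P(match) ≲ 10⁻¹⁰` at 1000 sequences × length 1000.

**Generation** is deterministic: candidates are enumerated in
lexicographic order over `alphabet^L`, filtered by `entropy_min`, and
admitted greedily when at least `distance_min` edits from every barcode
already admitted, until `count` barcodes exist or the pool is exhausted
(a warning, not an error). The emitted set is then ranked by robustness —
minimum edit distance to the rest of the set, descending — then by
entropy descending, then lexicographically; ids `bc.001…` follow the
final ranking. Greedy lexicographic admission is one of many valid
constructions of an edit-distance code; the set's *properties* (pairwise
distance, entropy, alphabet), not its exact membership, are the contract,
and the test suite checks exactly those.

The canonical pool used when a caller supplies none is the first 100
generated barcodes (`DEFAULT_POOL_COUNT`), cached per process: 100
anchors exceed any real scaffold, and the truncated generation costs
about a second where the full 949 takes minutes. Because generation is
deterministic, barcode ids resolve to the same sequences at
reconstruction time without shipping the pool alongside the FASTA.

**Collision checking** is exact-substring only: a barcode that occurs
verbatim in a gap-stripped input sequence is skipped and the next barcode
in rank order substituted, with the substitution reported. Fuzzy
collision thresholds would add a free parameter with no principled
default.

## Round-trip metadata

The displaced characters ride in the FASTA identifier:
`id|CB:col,bcid,char;…` with 1-based alignment columns. The delimiters
`|`, `;`, `,` never occur in amino-acid alphabets and survive every
aligner that preserves identifiers. Encode→decode is bit-exact
(property-tested). A record with a gap at a barcoded column still
receives the barcode and stores `-`: dropping such records would silently
lose sequences, and anchoring them keeps the round trip exact; they are
flagged in the run report so users can exclude them deliberately.
Replacing a non-cysteine residue warns but proceeds — the method applies
to any column of structurally homologous residues (e.g. catalytic
anchors), not only cysteines.

## Homology suggestion

Given a backbone-based (structure-derived) sequence alignment, cysteines
are taken as structurally homologous when they lie in the same or a
neighbouring column (`neighbour_window = 1` by default; a sub-3 Å
backbone shift appears as at most one column of displacement in such
alignments). Clustering is greedy left-to-right: a class seeds at the
leftmost unassigned cysteine column and absorbs, per other record, the
nearest unassigned cysteine within the window (nearer beats farther, left
beats right on ties). Greediness resolves adjacency chains (columns 5, 6,
7 across three records) deterministically in favour of the leftmost seed.
Output classes are labelled with roman numerals in column order and
marked `suggested`: confirming them is deliberately the user's decision,
the one manual step of the method. Sequences without structures are
assigned to the sub-group of their highest-scoring representative by
global pairwise alignment (ties by input order); an external search tool
can replace this by ranking representatives upstream.

## Built-in aligner

Gotoh affine-gap global alignment with BLOSUM62 (from Biopython's
substitution-matrix collection), `gap_open = 10`, `gap_extend = 1`; a gap
run of length `k` costs `open + (k−1)·extend`. Traceback tie-breaking is
fixed (residue pair ≻ gap in first sequence ≻ gap in second), so every
result is deterministic; optimality is verified in tests against full
enumeration of all alignments for short pairs. The multiple aligner is
progressive: all pairwise scores form a single-linkage order, the best
pair is aligned first, and each remaining sequence joins the profile
(column-vs-residue score = mean substitution score over the column's
non-gap characters). Profile alignment compares forward-pass expressions
bitwise during traceback, so floating-point column averages cannot
desynchronise the path. No claim is made about alignment quality on
non-barcoded sequences; the aligner exists so the pipeline is
self-contained, and the external-aligner adapter (subprocess with
`{in}`/`{out}` placeholders, validated for id and residue preservation)
is the route to production aligners.

## Reconstruction

Each record's expected barcodes are located as the minimal column span
whose gap-stripped content equals the barcode — aligners may split a
barcode with internal gaps; the span absorbs them. A barcode found zero
or two times is an error (corruption; fuzzy rescue is explicitly not
attempted). The span is overwritten with the stored original character at
its first column and gaps elsewhere; placement at the first column is an
arbitrary but deterministic convention, and after all-gap-column removal
it is invisible whenever the records agree. Span disagreement across
records is a warning, never an error: the alignment is still produced,
with the offending records named, because a hard failure on an imperfect
aligner would make the tool unusable exactly when the user most needs to
see the result.

## Loop profiling

Anchored columns cut each record into `k + 1` loops (both termini
included, possibly empty); gaps are stripped per loop. Hydropathy is the
arithmetic mean of Kyte–Doolittle values (GRAVY-style, so loops of
different lengths compare; a sum is available), `None`/`NA` for empty
loops. Net charge at neutral pH counts K/R as +1, D/E as −1, histidine
configurable (default 0), termini ignored since loops are internal
fragments; unknown residues count 0 with a log note. Both tables are
user-replaceable. Output is a plain CSV (`record_id, loop_index, length,
hydropathy, net_charge`) plus a text summary.

## Synthetic families

The generator emulates the regime that defeats naive aligners: a
conserved scaffold with divergent loops. An ancestor with `n_cysteines`
cysteines separated by uniform-random loops (default lengths 2–12)
produces `n_sequences` descendants by per-residue loop substitution
(default rate 0.4), one indel attempt per loop (default probability 0.5,
size 1–3), and optional cysteine loss (`missing_cysteine_rate`,
gap-deletion; default 0). Defaults describe a single divergent
defensin-like sub-group of 20 sequences on a 6-cysteine scaffold. All
randomness flows from one explicit `numpy` generator seeded by the
config; no global state.

Construction gives the truth for free: loops are padded per region, so
every scaffold cysteine of a class occupies exactly one known column.
Two deliberate simplifications: loop residues exclude cysteine (the
scaffold is then exactly the homology truth; real CRP loops occasionally
contain free cysteines, which would force the user-confirmation step the
generator bypasses), and mutations are i.i.d. rather than
phylogenetically correlated. Passing tests therefore demonstrate the
architectural guarantee — barcodes anchored, residues conserved, columns
restored — not aligner accuracy on real defensin data.

**Misalignment metric**: for each homology class, members are mapped into
a test alignment via residue ordinals and the most common column is the
modal column; the misalignment rate is the percentage of members
elsewhere. The truth alignment always scores 0 by construction.

## Problem sizes

The test suite and the acceptance script use the first 100 generated
barcodes and 20-sequence, 6-cysteine families: large enough that loops
diverge and naive alignment demonstrably misplaces cysteines, small
enough that the whole suite runs in well under a minute. A seed sweep in
the tests confirms 100 % cysteine retention is seed-independent when no
cysteines are missing.

## Known limitations

* Exact membership of any previously published default barcode list is
  not reproduced (the construction order is not part of the contract);
  the emitted set satisfies the same entropy/distance/match-probability
  properties.
* Reconstruction requires the same barcode pool (default or explicit
  CSV) that was used at barcoding time; mixing pools raises
  missing-barcode errors rather than guessing.
* The similarity-based sub-group assignment is a stand-in for a proper
  homology search; for large families use an external search tool and
  feed the resulting sub-groups in directly.
* Structure parsing is out of scope: the suggestion stage consumes a
  structure-derived FASTA alignment, not coordinates.
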