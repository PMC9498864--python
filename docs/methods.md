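# Methods

This note records the models, conventions and design choices behind
`cpfkit`, in the spirit of the methods documentation of packages like
scikit-bio or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic fixtures do and do not demonstrate.

## Hit curation (seqio)

Raw homology-search hits (standard 12-column tabular format) are curated in
three steps before any tree building:

* **E-value filter.** Strictly `evalue < threshold`, default `1e-15`. A hit
  at exactly the threshold is removed; the filter is idempotent and order
  preserving.
* **Deduplication.** Duplicate annotations of the same gene are collapsed
  *within one organism only*; identical sequences in different organisms
  are legitimate orthologs and are never merged. Default is exact-sequence
  identity; an optional near-duplicate mode (alignment identity ≥ 0.98,
  counted over all alignment columns) also collapses truncated isoforms.
  The longest member of a duplicate group is kept (ties broken by smallest
  id) — longest-isoform is the conventional proxy when curation notes are
  unavailable. The operation reports every removed→kept pair.
* **Taxonomic subsampling.** At most 5 organisms per order and 2 per
  family (defaults), so heavily sequenced taxa do not dominate the tree.
  Organisms on a keep list are retained first (an error is raised if the
  keep list alone violates a cap); remaining slots are filled in input
  order. Input order is the default because it is reproducible; a seeded
  random mode exists for simulation studies. All sequences of a retained
  organism are kept, and an organism lacking a rank value is unconstrained
  at that rank.

Sequences are uppercase strings over the 20 standard amino acids plus `X`
(unknown). The ambiguity codes `B`, `J`, `Z` are *rejected in sequences*
and reserved for motif patterns, which keeps pattern-matching semantics
unambiguous. `*` stop symbols are stripped on input.

## Motif model (motifkit)

A motif pattern is a string over the 20 amino-acid letters plus three
wildcard classes: `x` (any residue, including `X`), `B` = {D, N},
`J` = {I, L}, `Z` = {E, Q}. Pattern invariants: length ≥ 3, first
character concrete, at least half the positions concrete.

**Matching.** A window matches when every wildcard-class position matches
its class and the number of substitutions at concrete positions is at most
the pattern's mismatch budget (default 0). Two consequences worth stating
explicitly, since they are the tie-breaking choices of this implementation:

* a wildcard-class position never consumes mismatch budget — a residue
  outside the class fails the window outright;
* sequence `X` matches only pattern `x`; at a concrete position it counts
  as one mismatch.

All overlapping occurrences are reported, sorted by start; coordinates are
0-based half-open internally and converted to 1-based inclusive only in the
GFF3 emitter.

**Frequency tables.** For each (subfamily, motif) pair the tabulator
reports `n_present / n_total` as an integer percent, rounded half away from
zero (so 100/103 → 97%). A sequence counts once per motif regardless of
hit multiplicity. The display view suppresses cells below 50%, the
conventional reporting cutoff for subfamily motif panels.

**Consensus and discovery.** Subfamily sets are stacked into equal-length
rows by center-star alignment (every sequence aligned to the set medoid,
merged on the center's coordinates). Per column, the consensus takes the
most frequent residue when it reaches the column threshold (default 0.6)
among non-gap rows and at least half of all rows are non-gap; otherwise
`x`; majority-gap columns are dropped. Candidate motifs are consensus
windows of length ≥ 4 (the shortest useful diagnostic observed in this
family is a 4-mer), concrete at both ends, with wildcard fraction ≤ 1/3;
a candidate is accepted when its scan prevalence is ≥ 0.7 in its own
subfamily and ≤ 0.05 in every other subfamily, and only maximal windows
are emitted. Accepted patterns re-scanned against the input sets reproduce
those prevalence bounds by construction.

**Library.** The motif library is a TSV
(`name, pattern, subfamily, max_mismatches, source`). Patterns whose
sequences are published only in supplementary material (the α-helix
motifs, the MCRY/DCRY/CPD/DASH/PCRY panels, the CRY4 and MCRY-subtype
motifs) ship as *named placeholders* with empty patterns; they are skipped
by the scanner until the user supplies sequences. Shipped scannable
defaults are the eight main-text patterns (pl1–pl3, dm1, ppl1–ppl3, and
the 6-4 PL C-terminal tail motif).

## Distances and trees (phylokit)

* **Alignment.** True global (end gaps penalized) pairwise alignment under
  the Dayhoff-derived PAM100 matrix (bundled as a text data file from the
  standard NCBI matrix collection), affine gap costs: a gap of length L
  costs `10 + (L−1)·1`. Implemented on Biopython's `PairwiseAligner`; among
  co-optimal alignments the aligner's deterministic first traceback is
  used. PAM100 suits the moderately diverged within-family comparisons
  this pipeline makes; the matrix name, and the 10/1 costs, are exposed as
  parameters.
* **Distance.** Observed mismatch fraction `p` is counted over columns
  where both rows carry a residue (gap columns excluded; an all-gap
  comparison is an error). The Jukes–Cantor correction generalized to 20
  states is `d = −(19/20)·ln(1 − (20/19)·p)`. The correction diverges at
  `p = 0.95`; distances at or beyond `p_max = 0.95 − 1e-9` are capped at
  `d_cap = 10`, a value far larger than any within-family distance, so
  saturated pairs sort last without producing infinities.
* **Neighbor-Joining.** Standard Saitou–Nei: each round joins the pair
  minimizing `Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`; branch
  lengths from the usual formulas, negative lengths clamped to 0; exact
  ties in Q are broken by the lexicographically smallest pair of cluster
  keys (a cluster's key is its smallest leaf label), making the tree
  deterministic. The result is an unrooted tree (trifurcating root). On an
  additive matrix NJ returns the generating topology with exact branch
  lengths; the test suite verifies this on random trees, and cross-checks
  topologies against scikit-bio's independent NJ implementation.
* Distances are computed from pairwise alignments rather than one multiple
  alignment: pairwise is exactly reproducible and sufficient for NJ; the
  center-star stack exists solely to feed consensus derivation and makes
  no claim of MSA optimality.

## Classification (classify)

The reference panel holds one curated protein per subfamily (the eleven
labels: 6-4 PL, CPDI, CPDII, CPDIII, PPL, DASH, MCRY, DCRY, ACRY, PCRY,
PCRY-like). Assignment of a query:

1. candidate label = subfamily of the nearest reference by Jukes–Cantor
   distance (ties by reference id);
2. motif support per subfamily = fraction of that subfamily's library
   motifs with ≥ 1 hit in the query;
3. if the candidate's support is 0 while another subfamily reaches ≥ 0.5,
   the call is demoted to `unassigned` with the conflict flag set — the
   deterministic analogue of branches that cannot be assigned cleanly;
4. if the second-nearest reference disagrees and lies within a 5% relative
   margin of the nearest distance, the candidate is kept but flagged.

Nearest-reference distance approximates clade membership in the full tree
(manual clade inspection does not automate); an optional `tree_check` mode
builds the NJ tree of panel + query and flags disagreement between the
query's nearest tree leaf and the candidate. MCRY subtype calls (standard
"st" vs MCRY1/MCRY2) are purely data-driven: the subtype with the highest
support among user-supplied subtype motifs wins, with ties and all-zero
support defaulting to "st".

Repertoires are binary organism × subfamily matrices (presence = at least
one sequence with that label); unassigned sequences are tracked in an
`other` column so no sequence silently disappears.

## Prevalence (prevalence)

Organisms are grouped by their taxon at the requested rank (missing values
form an explicit `unranked` row, conserving counts); each cell is the
integer percent of the taxon's organisms possessing the subfamily, rounded
half away from zero. Rendering conventions: a count of exactly 0 renders
"-" (distinct from a nonzero count that rounds to 0%); the clade-summary
view masks cells at or below the display cutoff (default 10, strict
greater-than), and masking never alters the stored counts.

## Synthetic fixture (synthetic_data)

The generator emulates the *statistical shape* of a curated CPF survey,
not its biology:

* Per-subfamily sets are mutated copies of one random 500-aa scaffold
  (1000 aa for ACRY, whose internally duplicated proteins are roughly twice
  the family-typical length), point-mutated at 5% per site by default.
* Each diagnostic motif occupies a fixed scaffold site and is planted in
  exactly `round(rate · n)` sequences chosen by seeded shuffle
  (exact-count planting, not Bernoulli), so a configured prevalence is a
  deterministic property of the set, not an expectation. Wildcard positions
  are instantiated once per motif.
* Scaffolds are rejected until they contain no match of *any* library
  motif, and a mutated copy is redrawn if mutation accidentally creates a
  match of a non-planted motif; together these guarantee that a sequence
  has a hit iff the motif was planted — the truth table and the scanner
  agree exactly, and rate-0 motifs yield exactly zero hits.
* Default planting rates are the reported per-subfamily motif frequencies
  (pl1 74%, pl2 83%, pl3 97% in PCRY-like; dm1 70% in DCRY; ppl1 85%,
  ppl2 75%, ppl3 85% in PPL; the C-terminal tail motif 81% in 6-4 PL).
  Set sizes: 103 for PCRY-like (the reported set size), 100 for DCRY and
  6-4 PL and 20 for PPL — sizes at which whole-percent rates survive the
  plant-count/percentage round trip exactly.
* Mock taxa mirror the reported kingdom-level presence rates (e.g.
  Metazoa, n=497, MCRY 86%); presence flags are likewise planted by exact
  counts.
* Classification mode anchors each subfamily's scaffold at a synthetic
  reference (the scaffold itself enters the panel), mutates queries 5%
  from it and plants two diagnostic motifs per query. Subfamilies whose
  published diagnostics are supplementary-only get synthetic stand-in
  motifs (random concrete 8-mers, named `syn_*`, labelled synthetic).
* All randomness flows through named PCG64 substreams
  (`SeedSequence(seed, spawn_key=crc32(name))`), so output is
  byte-identical across platforms and call orders for a fixed seed.

**What passing tests show — and do not show.** Exact parameter recovery on
this fixture validates the *bookkeeping*: scanning, counting, rounding and
aggregation introduce no bias or off-by-one. Classifier recovery ≥ 99% on
the classification fixture validates the assignment logic under the
fixture's assumptions (queries are bounded-divergence copies of panel
references; subfamilies are mutually random). Real CPF sequences violate
these assumptions — subfamilies share the photolyase fold and are far from
mutually random, indels and domain gains/losses occur, and motif
prevalences vary continuously — so fixture results certify correctness of
the machinery, not expected accuracy on real data.

## Numerical and degenerate-input conventions

* Percent rounding: half away from zero everywhere (`floor(x + 0.5)` for
  x ≥ 0).
* Jukes–Cantor: `d(0) = 0` exactly; cap constants as above.
* NJ requires ≥ 3 labels; alignment of an empty sequence, an empty
  alignment stack, an empty reference panel, an empty motif library and an
  empty own-set in discovery are all immediate errors rather than silent
  degenerate output.
* Deduplication and the e-value filter are idempotent; no seqio operation
  ever increases the record count.

## Known limitations

* No bootstrap support, ML/Bayesian trees, or tree rooting.
* No PSSM/HMM motif models; patterns are exact-window wildcards with a
  substitution budget (no indels within a motif).
* Center-star stacking is a heuristic stand-in for a progressive MSA.
* The synthetic generator models neither indels, nor site-rate
  heterogeneity, nor gene duplication/loss along a phylogeny.
* Subfamily assignment uses one reference per subfamily; subfamilies with
  deep internal splits would benefit from multiple references per label,
  which the panel format does not currently express.
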