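# Methods

`barcodekit` implements the standard assessment workflow used to decide
whether a candidate DNA marker works as a species barcode for a group of
taxa: how well separated within-species and between-species distances are
(the "barcoding gap"), and how often simple identification rules assign
the right species when every sequence is queried against the rest.

## Distances

Pairwise distances are computed under **pairwise deletion**: for each pair
of aligned sequences, only columns where *both* carry a plain base
(A/C/G/T) are compared. Gaps and IUPAC ambiguity codes are treated as
missing and excluded — a conservative convention shared by common distance
tools. Two models are offered:

* the uncorrected p-distance, `p = (transitions + transversions) / n`;
* the Kimura 2-parameter (K2P) distance,

  `d = -1/2 · ln((1 − 2P − Q)·√(1 − 2Q))`,

  where `P` and `Q` are the transition (A↔G, C↔T) and transversion
  proportions among compared sites.

A pair is **undefined** — carried as an explicit state, never a sentinel
value — when fewer than `min_overlap` sites are compared (default 300,
the conventional floor for partial barcode sequences) or when the K2P
logarithm argument is non-positive (saturation). Undefined pairs are
excluded from every downstream summary and counted in the matrix
diagnostics. Whether other tools floor negative intermediate quantities
differently is not observable from their output; saturated pairs are rare
at barcoding divergences and are simply reported.

## Barcoding gap

Distances split into intraspecific (same effective label) and
interspecific sets; the gap statistic restricts the interspecific side to
**congeneric** pairs, since the nearest allospecific neighbour of a
specimen is almost always a congener and the gap is meaningless across
genera. Two ranges are reported:

* `total`: all defined pairs;
* `trimmed90` ("90% overlapping range"): the largest ⌈5%⌉ of
  intraspecific and smallest ⌈5%⌉ of congeneric interspecific
  observations are removed first. Trimming operates on pairwise
  *observations*, not per-species summaries, so the number of affected
  observations can be reported alongside the statistic; ceiling counts
  and remove-most-extreme-first tie-breaking make the trim deterministic.

Internally distances are proportions; exports multiply by 100 because gap
plots conventionally use percent.

## Identification criteria

Every sequence serves once as a query against all others (leave-one-out).

* **Best Match (BM)** — take the label(s) of the nearest defined
  reference(s). All-conspecific candidates: correct; a single wrong
  label: misidentified; mixed labels at an exact tie: ambiguous.
* **Best Close Match (BCM)** — BM gated on a threshold: if the best
  distance is not strictly below it, the query is a "no match". The
  threshold is the smallest defined interspecific distance of the dataset
  under the active label mode. The comparison is strict (`<`) because the
  threshold is itself realised by an allospecific pair; an inclusive
  comparison would admit a guaranteed wrong match, and with the strict
  rule BCM provably cannot misidentify (every strictly sub-threshold
  match is intraspecific by construction).
* **All Species Barcodes (ASB)** — judge the *set* of all references
  strictly within the threshold: empty → no match; any allospecific
  member → misidentified; otherwise correct only when the set holds at
  least two conspecific barcodes *and* every conspecific reference
  comparable to the query — else ambiguous ("only one conspecific
  barcode, or only a portion of them"). "Any allospecific member
  suffices for misidentification" is the stricter of the two possible
  readings and the one adopted here.

Percentages are computed over queries with at least one defined
comparison; excluded queries are listed so denominators are auditable.

## Trees

Neighbor joining (Saitou–Nei) is implemented in-package so two
conventions are pinned: equal Q-criterion ties resolve to the
lexicographically smallest id pair (platform-independent determinism),
and negative branch-length estimates are clamped to zero with the deficit
moved onto the sister branch, preserving path lengths. On additive
matrices the algorithm provably recovers the generating topology; the
test suite checks this against an independent library implementation.

Bootstrap supports resample alignment columns with replacement; each
replicate's distance matrix is rebuilt from precomputed per-column
per-pair counts (so a replicate costs one matrix–vector product plus one
NJ run), and the support of an internal edge is the percentage of
replicates containing the same unrooted bipartition. A replicate whose
matrix contains an undefined pair is redrawn (up to 100 attempts) so the
replicate count is preserved. Default is 1,000 replicates.

For rule-based identification the tree is midpoint-rooted (or rooted at a
designated outgroup, which is then pruned before scoring) and internal
edges of length ≤ `collapse_epsilon` (default 1e-9 substitutions/site)
are contracted into polytomies, so exactly-zero-length branches — e.g.
from identical sequences — do not present as resolved clades.

Two criteria sets score each leaf:

* **Hebert-style**: correct iff all conspecific leaves form a
  monophyletic group; sole representatives of a label (singletons) are
  ambiguous; conspecifics split across clusters is a misidentification.
* **Meier-style** (stricter), judged from the query's local context on
  the collapsed tree, with rules applied in order: no conspecifics →
  ambiguous; all-conspecific polytomy siblings → correct; all-conspecific
  sibling under a binary parent → correct if the siblings are a *proper
  subset* of the query's conspecifics ("one node into a clade of
  conspecifics"), ambiguous if they are the *complete* set (sister to all
  conspecifics); purely allospecific context → misidentified; mixed
  context → ambiguous (conservative: the criteria enumerate only pure
  cases).

The proper-subset/complete-set distinction is the module's central
interpretive decision; it is the only reading consistent with both
"one node into a clade of conspecifics is correct" and "sister to
conspecifics is ambiguous".

## Synthetic data generator

The generator emulates a small multi-species barcoding study:

* a **Yule** (pure-birth) species tree rescaled to a chosen root-to-tip
  height in expected substitutions/site. Draws whose shallowest split
  falls below 25% of tree height are rejected and redrawn: a raw Yule
  draw concentrates late splits near the present, which would decouple
  the height parameter from the between-species divergence it exists to
  control.
* **star genealogies within species**, chosen over a coalescent for
  analytic transparency (the pipeline consumes distances, not
  genealogies). Each specimen's terminal branch is drawn
  Exponential(mean = `intra_height`) rather than fixed: with a fixed
  shared depth the expected minimum interspecific distance could never
  fall below the expected maximum intraspecific distance, so designed
  *overlapping* scenarios would be unreachable. `intra_height = 0` still
  yields identical conspecific sequences.
* **site-wise evolution** under the two-rate Kimura process (default
  transition/transversion rate ratio `kappa = 2.0`, an unremarkable
  mid-range value), using the exact closed-form transition probabilities
  per branch — verified in the tests against the matrix exponential of
  the rate matrix — with rates normalized so branch lengths are expected
  substitutions per site.

Defaults describe a well-separated study: 5 species × 4 specimens,
1,000 sites, `intra_height = 0.005` vs `species_tree_height = 0.20`.
`scenario_gap(width)` returns a config whose realized gap is
approximately `width`, using a fixed heuristic calibration (shallowest
split ≈ H/3; realized max-intra ≈ 4·`intra_height`); negative widths
produce overlapping distributions. `singleton_fraction` reduces that
fraction of species to a single specimen.

What the generator does **not** emulate: indels and alignment error (all
sequences are generated aligned), rate heterogeneity across sites,
within-species coalescent structure, introgression, and sequencing
error. Passing tests therefore demonstrate the correctness of the
assessment machinery under a clean substitution process, not robustness
to alignment artefacts or population-genetic complications in real
marker data.

## Known limitations and numerical choices

* With nonzero intraspecific divergence, NJ resolves within-species star
  genealogies using sampling noise alone; small positive internal edges
  (~1e-3 at 1,000 sites) survive the default collapse threshold, and one
  basal specimen per pectinate species clade then scores
  "sister to all conspecifics" (ambiguous) under the Meier rules. Meier
  success therefore sits below 100% whenever conspecific sequences
  differ — matching the behaviour of these criteria on real data — and
  reaches 100% only when conspecific sequences are identical. One
  acceptance test documents this boundary.
* The problem sizes used by the test suite and `scripts/acceptance.py`
  (20-sequence datasets, 1,000 sites, 100–200 bootstrap replicates)
  were chosen so a full run completes in seconds while keeping
  Monte-Carlo error well inside the asserted margins.
* Ties at the minimal BM distance, at the trim cut and in the NJ
  Q-criterion are all resolved deterministically (documented above), so
  identical inputs and seeds give byte-identical reports.
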