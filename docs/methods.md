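# Methods

## Reference knowledge base

The package ships a hand-checked TSV transcription of the published
reference tables for experimentally characterized mushroom STSs:
`table1_reference.tsv` (174 rows: gene name, species, GenBank/JGI
accession, ordered product list, clade, citation key) and
`table2_motifs.tsv` (172 rows: printed aspartate-rich Motif I string,
NSE-region Motif II string, Pfam domain labels).  Quirks of the printed
tables are preserved rather than repaired: duplicate accessions (e.g.
KAH9071064.1 appears twice), "not available" accessions, blank product
cells, and the two entries marked as not analyzed ("\\"), which map to
clade `unassigned` and are excluded from clade summaries.  The two tables
are joined by exact gene name; motif rows without a dataset partner are
retained and surfaced (`ReferenceDB.unmatched_motif_rows`) instead of
being dropped.

Product strings are normalized deterministically — lowercase, Greek
letters spelled out (α→alpha, Δ→delta, Ʈ→tau), superscripts inlined
(Δ^6^-protoilludene → delta6-protoilludene), whitespace collapsed to
hyphens, and a one-entry alias table (virifloridol → viridiflorol) — while
the printed string is kept on every record.  Product lists split on ";"
and on ", " (two printed rows use comma separators; commas inside chemical
names are never followed by a space, so the split is unambiguous).  A
trailing "etc." is dropped; "ND" and blank cells give empty lists;
"unknown sesquiterpene(ol)" entries are flagged and never counted as
predictable products.

Role semantics: the first-listed product is the enzyme's *major* product,
matching the source's main-product/side-product prose; *minor* means
present at rank ≥ 2; *sole* means the only listed product.

Two printed summary numbers are documented but deliberately not asserted
anywhere: the clade-II species count (printed 22; the distinct-binomial
tally over the transcription gives 21) and the MEME-derived motif coverage
numbers (NSE in 161/172, DExxD in 87), which depend on the discovery
tool's unstated match criteria — strict consensus matching over the
printed strings gives 158 and 86.  The `DD(N)xxD` count (53) is exactly
reproducible and is asserted.

## Motif model

Motif discovery is out of scope; the *discovered consensus patterns* are
the model.  The notation grammar (uppercase = fixed residue, `x` = any,
`(A/B/C)` = alternation) compiles to per-position residue sets; scanning
reports all matches including overlapping ones, so the primitive stays
total and unambiguous.  Picking "the" catalytic pair is a separate,
configurable step: among aspartate-rich hits strictly upstream of NSE hits
with spacing in a window (default 60–260 residues — an explicit knob,
since characterized STSs place the NSE region an "appropriate" but not
fixed distance downstream), the pair with spacing closest to the window
midpoint wins.  Aspartate-region classification tests sub-patterns in
order `DExxD`, `DD(N)xxD`, then the generalized `D(D/E/N)xx(D/E)`
("other-variant"); everything else, including absent fields, is "absent" —
a partition by construction.

Candidate screening keeps sequences inside a length window (default
250–700 aa, bracketing known ~300–600 aa STSs) that carry an NSE or
aspartate-rich hit.  This replaces a similarity-search step whose
thresholds the source never stated; both knobs are exposed in
`ScanConfig`.

## Substitution model and distances

The packaged JTT model (`data/jtt_model.tsv`) holds the published
Jones–Taylor–Thornton (1992) exchangeability counts and stationary
frequencies as distributed in standard `jtt.dat` model files.  The rate
matrix is built as Q_ij = s_ij·π_j, diagonal set so rows sum to zero, and
scaled so the mean stationary rate −Σπ_iQ_ii is 1: distances are expected
substitutions per site.  P(t) = exp(Qt) comes from the eigendecomposition
of the symmetrized matrix D^½QD^(−½) (exact for a reversible Q), clipped
at zero to absorb round-off.

All distances use pairwise deletion: a pair of rows is compared only on
columns where neither carries a gap, and the ambiguity character X is
removed the same way (it carries no information).  Pairs with zero
comparable sites get NaN and are reported as undefined.  `p` is the
mismatch proportion; `poisson` is −ln(1−p); `jtt-ml` maximizes
Σ_sites log(π_a·P_ab(t)) over t ∈ [1e−8, 10] by bounded scalar
optimization (tolerance 1e−6 on t, 200-iteration cap; identical rows
short-circuit to exactly 0).  No rate heterogeneity across sites is
modeled (the source analysis used none).

## Neighbor joining and bootstrap

Saitou–Nei agglomeration with Studier–Keppler Q selection; branch lengths
from the standard two-point formulas with negative estimates clamped to
zero; the final three clusters are resolved around a central node, so the
returned tree is unrooted and displayed with a trifurcating root.
Determinism without any seed: Q-ties are broken by the lexicographically
smallest pair of cluster representatives (a cluster's representative is
its smallest leaf label).  On additive matrices the generating topology
and branch lengths are recovered exactly (property-tested against path
metrics of random trees, and cross-checked against scikit-bio's
independent NJ implementation on noisy matrices).

Bootstrap: replicate r resamples alignment columns with replacement using
the derived stream `default_rng([seed, r])` — replicates are independent
of execution order — rebuilds the tree, and the full-data tree's
non-trivial bipartitions are scored by the fraction of completed
replicates containing them.  Replicates hitting an undefined pair are
skipped and logged, and the support denominator uses completed replicates
only.  Supports are attached as internal-node labels in Newick output.

## Clade assignment and product prediction

Queries are mapped into the reference coordinate frame by affine-gap
global alignment (BLOSUM62, open −10, extend −0.5) against the reference
alignment's majority-rule consensus; query residues land in their
consensus partner's columns and insertions relative to the consensus are
dropped.  This keeps the pipeline free of external aligners; pre-aligned
query rows are accepted as an alternative.  The consensus-profile mapping
is adequate for family-level placement but is *not* a full profile HMM:
queries far more diverged than the reference radiation may lose columns.

Methods: `nn` takes the nearest reference's clade (confidence 1 − d₁/d₂,
a documented separation heuristic); `knn` (default, k=5) takes the
majority of the k nearest, ties broken by smaller mean distance then
lexicographic clade label, confidence = vote share; `placement` builds an
NJ tree of references plus query and reads the majority clade of the
query's sister group.  Because the NJ tree is unrooted, the sister group
is taken as the direction from the query's attachment node holding the
fewest leaves — the local cluster, not the tree remainder; confidence is
the share of bootstrap placements agreeing when bootstrapping is
requested, else 1.0.  The clade→(substrate, ring closure, intermediate)
map is a frozen constant covering exactly clades I–IV; following the
four-clade scheme adopted here, TRI5-like sequences that other studies
put in a fifth clade are labeled IV.

Product prediction collects the major (first-listed) products of the k
nearest references, skipping entries with no detected or unidentified
products, and ranks candidates by supporting-neighbor count, then
alphabetically.  Minor products can be included behind a flag.  How the
original analysis turned tree position into product predictions was never
formalized; this neighbor-majority rule is an explicit reconstruction and
should be read as such.

## Synthetic benchmark

The generator emulates the structure the classifier assumes, not real
STS sequence idiosyncrasy: a stationary-frequency root diverges into four
clade ancestors (each a CTMC run of half the configured backbone
divergence, so ancestor pairs sit at the full divergence), each ancestor
radiates on a random bifurcating tree (uniform random joins, exponential
branch lengths), and clade-appropriate motif strings sampled from the
packaged reference table (DExxD-family for clades I–III, DD(N)xxD-family
plus TRI5-like NSE strings for clade IV) are planted at offsets drawn
once per clade (aspartate window 90–110, NSE window 215–240) and held
invariant during evolution.  Defaults — 4 × 12 sequences of 350 aa,
backbone divergence 1.0, intra-clade branch mean 0.08, 20 decoys, no
indels — mirror the reference set's scale (dozens of sequences, ~300–600
aa enzymes) while keeping a full run in seconds.  Optional indels delete
per-family column blocks outside motif windows so pairwise deletion has
real work to do.

Decoys are i.i.d. draws from the JTT stationary frequencies,
rejection-sampled until they contain no aspartate-rich or NSE consensus
match.  This deliberately departs from pure i.i.d. sampling (about a
quarter of unconstrained 350-aa stationary draws contain a chance
`D(D/E/N)xx(D/E)` match) so that the candidate screen's truth labels are
unambiguous; consequently the benchmark measures the screen's behavior on
motif-free backgrounds, not its false-positive rate on arbitrary
proteins.

Everything is deterministic under (config, seed): all randomness flows
through `numpy.random.default_rng` substreams keyed `[seed, component]`,
so outputs are byte-identical across runs and platforms.

What passing the benchmark does and does not show: simulated families are
much cleaner than real STS clades — no domain shuffling, no alignment
error, no compositional bias beyond JTT stationarity, motifs perfectly
conserved — so held-out accuracy ≥ 0.95 here demonstrates the machinery
is correct and calibrated, not that real-genome predictions reach that
accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen as the package's own defaults: 200 random additive matrices of
4–8 taxa for NJ exactness, 10,000 sites per simulated pair for distance
calibration (sampling error well under the 10% check), 500 random
sequences for the motif oracle sweep, and the default benchmark with a
20% hold-out for end-to-end accuracy.  Bootstrap replicate counts are
free parameters; published-scale analyses use 1000, the tests use small
counts since determinism and support arithmetic, not support values, are
under test.  Branch lengths and distances serialize at 6 decimals;
likelihood P(t) entries are floored at 1e−300 before logs; NJ tie-breaks
and all rankings are deterministic (documented above), so every artifact
is bit-reproducible under a fixed seed.

## Known limitations

- No multiple-sequence-alignment construction: the pipeline consumes an
  alignment; reference alignments must be built externally.
- The consensus-profile query mapping degrades for queries without close
  relatives in the reference alignment.
- Equivalence with any particular legacy phylogenetics GUI's JTT-distance
  implementation is not promised — only model-consistent estimation
  (verified by simulation recovery).
- Motif scanning is consensus-based; it will miss degenerate motifs a
  profile HMM would catch, and the printed motif strings it classifies
  are as-printed, including truncated entries.
- Genome-mining runs against real assemblies need the user to supply the
  proteome FASTA; no downloading is performed.
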