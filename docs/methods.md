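# Methods

## The knowledge store

`knowfilter` consults a local, single-file embedded relational database
(SQLite) rather than live external services, so analyses are fully
reproducible offline. The store holds seven entity kinds: sources, groups,
group members, genes with 1..n genomic regions, aliases, SNP loci, and
rs-merge records. It is populated from a tab-separated plain-text
knowledge-definition format, which keeps fixtures and hand-built stores
human-readable and diffable. Referential integrity (members → groups →
sources, alias targets → genes) and merge-chain acyclicity are validated
after all files are read, so neither record order nor file order affects the
resulting store. A `finalize` step flags the file read-only and compacts it,
making archived stores safe provenance records; every mutating call on a
finalized store raises, while queries are unaffected.

Conventions applied throughout:

* all coordinates are 1-based, fully closed intervals;
* rs-merge chains are followed transitively (with cycle rejection at
  ingest), and an rs number with no merge record — including one entirely
  unknown — maps to itself, so unmatched input surfaces as blank annotation
  rows rather than errors;
* each gene's own symbol and id are registered as symbol-type aliases at
  ingest, so plain symbols always resolve even in terse hand-written
  bundles;
* per-chromosome interval trees over gene regions back all containment and
  overlap queries.

## Ambiguity resolution

A group member is a bundle of identifiers that should denote one thing. Its
*candidate* genes and their supports are: with any protein identifier
present, the union of the protein identifiers' genes (non-protein
identifiers discarded), support = number of protein identifiers naming the
gene; otherwise the union over gene-type identifiers, support = number of
identifiers naming the gene. The *quality* score replaces each identifier's
unit vote by `1/|targets|`; the inverse-target-count weight is the simplest
strictly decreasing choice consistent with preferring names that denote only
one or two genes. Quality arithmetic uses exact rationals
(`fractions.Fraction`) so argmax ties are decided exactly.

Resolution first narrows candidates to the heuristic's winners (`none`
keeps all, `implication`/`quality` take their argmax with ties kept as
co-winners, `any` unions both argmax sets — including the never-yet-observed
case where the two heuristics each pick a different single winner). A single
survivor is always included; multiple survivors are all included under
permissive mode and dropped under strict mode. This yields the containment
chain *strict ⊆ permissive ⊆ full candidate set* for every member and
heuristic, which the tests assert. Members whose identifiers are entirely
unknown resolve to the empty set with a logged report rather than aborting;
the four-value disposition vocabulary (`unambiguous`, `heuristic_resolved`,
`dropped_strict`, `included_all_permissive`) covers them via the mode in
force.

Ambiguous names in *user input* are governed separately by
`ALLOW_AMBIGUOUS_GENES` / `ALLOW_AMBIGUOUS_GROUPS`: all matches or none,
with a warning either way and an optional detailed TSV report
(`--report-invalid-input`). Heuristic-resolved genes are not distinguished
in primary output — only in the report file — so strict-mode reruns remain
the way to audit the consequences of ambiguity.

## Query semantics

The six data types sit on a four-level chain: `snp`/`position` (loci),
`gene`/`region` (intervals), `group`, `source`. A filter result is the set
of tuples over the requested types that are consistent with every supplied
input (types with no input range over the whole store) and linked between
every pair of types at the same level or at adjacent *present* levels;
non-neighbouring constraints join through genes (e.g. a SNP is linked to a
group when some gene contains the SNP and belongs to the group). Positions
are degenerate one-bp regions for gene mapping; SNP inputs are merge-
normalized first. Percent overlap is measured against the input region's
length — the CNV is the object being classified, not the gene. Filter rows
are deduplicated and sorted lexicographically by their printed fields for
reproducible diffs; annotation preserves input order, repeats an item once
per match, and emits one all-blank row (empty TSV fields, no NA token) for
an item with no match. Annotating types that were not supplied as input
first materializes the filtered subject set, then annotates it.

The engine enumerates candidate tuples level by level with early pruning;
store sizes in the intended use (one query's joined universes) keep this
comfortably interactive, and randomized-store tests check it against an
independent exhaustive enumerator.

## Modeling

Candidate genes are whatever `filter_query(inputs, (gene,))` returns, so
"genes containing at least one input SNP" and "all genes" (empty input) fall
out of one definition. A group supports a pair at most once regardless of
how many members implicate each gene; the two same-named `gray` groups are
distinct groups from distinct sources and count as such. Ranking is
descending lexicographic on `(source_count, group_count)` — sources are the
scarcer, stronger evidence and are printed first — with the canonical gene
pair as tie-break. The cutoff takes independent minima `S[-G]`; a bare `S`
implies `(S, 1)` because `group_count ≥ source_count` always holds. SNP
expansion pairs the SNPs of the two genes (restricted to the supplied SNP
list when one is given, gene windows honoured); self-pairs are excluded, so
a SNP inside both genes of a model contributes to both sides but never to a
pair with itself. Region expansion is the same construction over input
regions mapped by the overlap policy. No statistical testing of models is
performed or implied: the output is a prioritized hypothesis list.

## The simulated knowledge base

The bundled store is entirely synthetic and frozen — no randomness, so
rebuilding it is byte-identical. Its structure packs the situations the tool
must handle into 13 genes: an overlapping gene pair sharing a SNP (`H`/`I`
with rs24), a SNP-less gene (`F`), a multi-region gene (`M`), a multi-locus
SNP (rs30), intergenic SNPs, a retired rs (90 → 24), ambiguous aliases
(`DE` → {D, E}; three-identifier members in `magenta`, `yellow`,
`gray/black`), duplicate group names across sources (the two `gray`
groups), and protein-identifier members including one whose two protein ids
target different gene sets. Coordinates and the membership of the groups
not pinned down by the worked examples are inventions, chosen once and
frozen. The generator emulates the *relational* structure of real
knowledge, not its scale or biology: genes are kilobase toys, there is no
linkage structure, identifier noise, or build mismatch, so passing tests
demonstrate correctness of the algorithms, not robustness to real-source
curation errors.

## Configuration and numerical choices

Options merge lowest-to-highest: built-in defaults, configuration files in
command-line order, explicit flags; the effective configuration is
serialized into the `.log` sidecar (and round-trips: re-running from it
reproduces identical output bytes). Defaults are the conservative corner:
strict mode, no heuristic, ambiguous inputs dropped, gene window 0 bp,
region overlap ≥ 1 base. All tallies are integer; the only non-integer
arithmetic (quality weights) is exact-rational. Determinism everywhere:
sorted iteration orders, canonical pair orientation, and tie-breaks by
printed representation.

Problem sizes in the test suite and acceptance script are those of the
bundled store plus randomized stores of at most ~20 entities with exhaustive
brute-force oracles (pair scoring by full group iteration, filtering by full
tuple enumeration) and 200 sampled protein-only members for the heuristic-
equivalence rate; these sizes make every brute-force check exact.

## Known limitations

* One genome-build label per store file; no liftover — inputs must match
  the store's build.
* Groups belong to exactly one source; n-wise (>2) models, permutation
  significance of implication scores, and genotype-data handling are out of
  scope.
* Membership after resolution is binary; heuristic confidence is not
  propagated into implication counts.
* Name matching is exact (case-sensitive); there is no fuzzy matching.
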