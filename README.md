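# knowfilter

Knowledge-driven filtering, annotation, and pairwise interaction-model
generation for genomic data.

Genome-scale association studies face a steep multiple-testing burden, and
exhaustive SNP×SNP interaction scans are usually intractable. `knowfilter`
lets researchers put accumulated biological knowledge — pathways, ontology
terms, protein families, curated interactions — in front of the statistics:
it compiles that knowledge into a single local store and uses it to

* **filter** lists of genomic entities against each other (e.g. keep only
  the SNPs falling inside a given set of genes),
* **annotate** lists with connected entities (positions, genes, regions,
  groups, sources), carrying unmatched items through with blank columns, and
* **generate models**: ranked candidate gene–gene (and derived SNP–SNP or
  region–region) interaction pairs supported by prior knowledge, for
  downstream statistical testing with whatever method the analyst prefers.

## The implication index

Two genes that co-occur in many groups, drawn from several independent
knowledge sources, are plausible interaction partners. For an unordered gene
pair $(g_1, g_2)$, let $\mathcal{G}$ be the set of groups whose resolved
membership contains both genes and $\mathcal{S}$ the set of sources owning
those groups. The pair's implication index is the tally

$$\text{index}(g_1, g_2) = (|\mathcal{S}|,\ |\mathcal{G}|), \qquad
  \text{printed } \texttt{S-G},$$

so `2-3` means the pair recurs in three groups from two sources. Models are
ranked by descending $(|\mathcal{S}|, |\mathcal{G}|)$; a cutoff trades the
number of models to test against their prior support.

Because sources name group members ambiguously (one member may carry several
identifiers, and one identifier may name several genes), membership is
resolved under a configurable policy: *strict* (drop anything ambiguous),
*permissive* (keep every candidate), or the *implication* / *quality*
heuristics, which pick the gene named by the most identifiers, optionally
weighting each identifier by $1/|\text{targets}|$. Protein identifiers
override gene identifiers within a member and legitimately map to several
genes, which makes the two heuristics provably equivalent there.

## Six data types

Queries relate any combination of **SNP** (rs number), **position**
(chromosome + 1-based bp), **region/CNV** (chromosome + start + end, closed),
**gene**, **group**, and **source** along the containment chain
`snp/position — gene/region — group — source`. Loci map to genes by closed-
interval containment with an optional symmetric window; regions map to genes
by overlap — at least N bases (default one single base) or at least P% of
the region's length. Retired rs numbers are normalized through merge records
before matching.

## Worked example

The package ships a small frozen simulated knowledge base (3 sources, 11
groups, 13 single-letter genes on 3 chromosomes, 21 SNPs) for exploring the
tool. Filtering its chromosome-1 SNP list by the gene list `{A, C}`:

```bash
knowfilter --knowledge src/knowfilter/data/simulated_kb.txt \
    --snp rs11 --snp rs12 --snp rs13 --snp rs15 --snp rs16 \
    --gene A --gene C --filter snp
```

```
snp
rs11
rs12
rs15
rs16
```

rs13 is intergenic, so four of the five SNPs survive. Asking for SNP–SNP
models from the same SNP list instead:

```bash
knowfilter --knowledge src/knowfilter/data/simulated_kb.txt \
    --snp rs11 --snp rs12 --snp rs13 --snp rs15 --snp rs16 --model snp
```

```
entity_a	entity_b	implication_index	source_count	group_count
rs11	rs15	2-3	2	3
rs11	rs16	2-3	2	3
rs12	rs15	2-3	2	3
rs12	rs16	2-3	2	3
```

The SNPs map to genes `A` and `C` (gene `F` on the same chromosome holds no
SNPs and is excluded); the single gene model `(A, C)` is supported by three
groups from two sources — index `2-3` — and expands to the four cross pairs
of the SNPs in each gene. Options can equally come from configuration files
(`KEY value` lines; later files override earlier ones, flags override all
files), so a saved configuration is a complete record of a run.

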