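"""Knowledge-driven pairwise interaction-model generation.

Two genes that recur together across many groups — pathways, ontology terms,
protein families, interaction pairs — and across several independent
knowledge sources are plausible candidates for a biological interaction.
The *implication index* quantifies that prior support for an unordered gene
pair as ``source_count-group_count``: the number of distinct sources owning
a group in which both genes co-occur, and the number of such groups.  A
score printed ``2-3`` means the pair appears in three groups drawn from two
sources.

Gene models can then be expanded to SNP-SNP models (all cross pairings of
the SNPs contained in the two genes) or to region-region models (all cross
pairings of input regions mapping to the two genes), each inheriting the
parent pair's index.  Candidate-model ranking is descending lexicographic on
``(source_count, group_count)`` with a canonical gene-pair tie-break, so
output order is reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .ambiguity import AmbiguityPolicy, group_genes
from .engine import (
    GeneWindow,
    OverlapPolicy,
    TypedInput,
    filter_query,
    map_region_to_genes,
)
from .errors import QueryError
from .store import KnowledgeStore


@dataclass(frozen=True)
class ImplicationIndex:
    """Prior-knowledge support of a gene pair, printed ``S-G``."""

    source_count: int
    group_count: int

    def __post_init__(self):
        if not (1 <= self.source_count <= self.group_count):
            raise QueryError(
                f"invalid implication index {self.source_count}-{self.group_count}"
            )

    def __str__(self) -> str:
        return f"{self.source_count}-{self.group_count}"

    @property
    def rank_key(self):
        return (-self.source_count, -self.group_count)


@dataclass(frozen=True)
class GeneModel:
    gene_a: str
    gene_b: str
    index: ImplicationIndex
    supporting_groups: frozenset[str]

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise QueryError("gene models must be stored with gene_a < gene_b")


@dataclass(frozen=True)
class SnpModel:
    rs_a: int
    rs_b: int
    parent: GeneModel

    @property
    def index(self) -> ImplicationIndex:
        return self.parent.index


@dataclass(frozen=True)
class RegionModel:
    region_a: tuple[str, int, int]
    region_b: tuple[str, int, int]
    parent: GeneModel

    @property
    def index(self) -> ImplicationIndex:
        return self.parent.index


def _pair_support(
    store: KnowledgeStore, policy: AmbiguityPolicy
) -> dict[tuple[str, str], set[str]]:
    """Map each unordered gene pair to the groups whose resolved membership
    contains both genes.  A group supports a pair at most once, however many
    of its members implicate each gene."""
    support: dict[tuple[str, str], set[str]] = {}
    for gid in store.group_ids():
        genes = sorted(group_genes(store, gid, policy))
        for a, b in itertools.combinations(genes, 2):
            support.setdefault((a, b), set()).add(gid)
    return support


def implication_index(
    g1: str,
    g2: str,
    store: KnowledgeStore,
    policy: AmbiguityPolicy = AmbiguityPolicy(),
) -> ImplicationIndex | None:
    """Implication index of an unordered gene pair, or None without support."""
    if g1 == g2:
        raise QueryError("a gene cannot form a model with itself")
    known = store.gene_ids()
    for g in (g1, g2):
        if g not in known:
            raise QueryError(f"unknown gene {g!r}")
    pair = (min(g1, g2), max(g1, g2))
    groups = [
        gid
        for gid in store.group_ids()
        if pair[0] in group_genes(store, gid, policy)
        and pair[1] in group_genes(store, gid, policy)
    ]
    if not groups:
        return None
    sources = {store.group_source(g) for g in groups}
    return ImplicationIndex(len(sources), len(groups))


def gene_models(
    inputs: Sequence[TypedInput],
    store: KnowledgeStore,
    policy: AmbiguityPolicy = AmbiguityPolicy(),
    cutoff: tuple[int, int] | None = None,
    window: GeneWindow = GeneWindow(),
    overlap: OverlapPolicy = OverlapPolicy(),
) -> list[GeneModel]:
    """Ranked pairwise gene models supported by the knowledge store.

    Candidate genes are those consistent with every supplied input (for a SNP
    list: genes containing at least one input SNP); with no inputs, every
    known gene is a candidate.  Every unordered candidate pair co-occurring
    in at least one resolved group becomes a model; ``cutoff`` is an optional
    ``(min_sources, min_groups)`` floor.
    """
    candidates = {
        row[0]
        for row in filter_query(list(inputs), ("gene",), store, policy, window, overlap)
    }
    support = _pair_support(store, policy)
    models = []
    for (a, b), groups in support.items():
        if a not in candidates or b not in candidates:
            continue
        sources = {store.group_source(g) for g in groups}
        index = ImplicationIndex(len(sources), len(groups))
        if cutoff is not None and (
            index.source_count < cutoff[0] or index.group_count < cutoff[1]
        ):
            continue
        models.append(GeneModel(a, b, index, frozenset(groups)))
    models.sort(key=lambda m: (*m.index.rank_key, m.gene_a, m.gene_b))
    return models


def _snps_in_gene(
    store: KnowledgeStore,
    gene: str,
    window: GeneWindow,
    restrict: frozenset[int] | None,
) -> set[int]:
    regions = store.gene_regions(gene)
    w = window.flank_bp
    snps: set[int] = set()
    for rs, chrom, pos in store.all_loci():
        if restrict is not None and rs not in restrict:
            continue
        for rchrom, start, end in regions:
            if chrom == rchrom and start - w <= pos <= end + w:
                snps.add(rs)
                break
    return snps


def expand_to_snp_models(
    models: Sequence[GeneModel],
    snp_input: TypedInput | None,
    store: KnowledgeStore,
    window: GeneWindow = GeneWindow(),
) -> list[SnpModel]:
    """Expand ranked gene models into all cross pairings of contained SNPs.

    When a SNP input is supplied, only its (merge-normalized) SNPs are
    eligible.  A SNP falling in both genes of a model contributes to both
    sides but never pairs with itself; pairs are unordered and deduplicated
    per model, stored with ``rs_a < rs_b``.
    """
    restrict = None
    if snp_input is not None:
        restrict = frozenset(store.current_rs(rs) for rs in snp_input.items)
    out: list[SnpModel] = []
    for model in models:
        sa = _snps_in_gene(store, model.gene_a, window, restrict)
        sb = _snps_in_gene(store, model.gene_b, window, restrict)
        pairs = {
            (min(a, b), max(a, b)) for a in sa for b in sb if a != b
        }
        out.extend(SnpModel(a, b, model) for a, b in sorted(pairs))
    return out


def expand_to_region_models(
    models: Sequence[GeneModel],
    region_input: TypedInput,
    store: KnowledgeStore,
    overlap: OverlapPolicy = OverlapPolicy(),
) -> list[RegionModel]:
    """Expand gene models into cross pairings of input regions.

    Each pair joins one input region mapping to ``gene_a`` with one mapping
    to ``gene_b`` under the overlap policy; a region overlapping both genes
    never pairs with itself.
    """
    region_genes = {
        region: map_region_to_genes(region, store, overlap)
        for region in dict.fromkeys(region_input.items)
    }
    out: list[RegionModel] = []
    for model in models:
        ra = [r for r, genes in region_genes.items() if model.gene_a in genes]
        rb = [r for r, genes in region_genes.items() if model.gene_b in genes]
        pairs = {
            tuple(sorted((a, b))) for a in ra for b in rb if a != b
        }
        out.extend(RegionModel(a, b, model) for a, b in sorted(pairs))
    return out
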