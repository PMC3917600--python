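"""Filtering and annotation over the six supported data types.

The engine understands six entity types — ``snp``, ``position``, ``region``,
``gene``, ``group``, ``source`` — arranged in a containment chain::

    snp / position  —  gene / region  —  group  —  source

SNPs and positions are point loci; genes and regions are chromosome
intervals; groups collect genes; each group belongs to one source.  A filter
query asks for every combination of entities of the requested output types
that is consistent with all supplied input lists and connected along the
chain; an annotation query walks an input list in order and appends the
connected entities to each item, leaving the columns blank for items that
match nothing.

Cross-chain constraints (a SNP list combined with a group list, say) are
joined through genes: two entities at non-neighbouring levels are connected
when some gene links them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .ambiguity import (
    AmbiguityPolicy,
    group_genes,
    resolve_input_genes,
    resolve_input_groups,
)
from .errors import KnowledgeError, QueryError
from .store import KnowledgeStore, chromosome_key

TYPES = ("snp", "position", "region", "gene", "group", "source")

#: position in the containment chain (same level = directly comparable kinds)
LEVEL = {"snp": 1, "position": 1, "gene": 2, "region": 2, "group": 3, "source": 4}


@dataclass(frozen=True)
class GeneWindow:
    """Symmetric flank in base pairs added to gene boundaries for locus tests."""

    flank_bp: int = 0

    def __post_init__(self):
        if self.flank_bp < 0:
            raise KnowledgeError("gene window must be non-negative")


@dataclass(frozen=True)
class OverlapPolicy:
    """How much a region must overlap a gene to map to it.

    ``kind='bases'`` requires at least ``threshold`` overlapping base pairs
    (default 1: a single shared base suffices); ``kind='percent'`` requires
    the overlap to cover at least ``threshold`` percent of the *input
    region's* length.
    """

    kind: str = "bases"
    threshold: float = 1

    def __post_init__(self):
        if self.kind not in ("bases", "percent"):
            raise KnowledgeError(f"unknown overlap kind {self.kind!r}")
        if self.threshold <= 0 or (self.kind == "percent" and self.threshold > 100):
            raise KnowledgeError(f"invalid overlap threshold {self.threshold!r}")


def _norm_snp(item) -> int:
    if isinstance(item, str):
        item = item.strip()
        if item.lower().startswith("rs"):
            item = item[2:]
        item = int(item)
    if item <= 0:
        raise KnowledgeError(f"invalid rs number {item!r}")
    return item


def _norm_position(item) -> tuple[str, int]:
    chrom, pos = item
    pos = int(pos)
    if pos < 1:
        raise KnowledgeError(f"invalid position {item!r}")
    return (str(chrom), pos)


def _norm_region(item) -> tuple[str, int, int]:
    chrom, start, end = item
    start, end = int(start), int(end)
    if start < 1 or start > end:
        raise KnowledgeError(f"invalid region {item!r}")
    return (str(chrom), start, end)


_NORMALIZERS = {
    "snp": _norm_snp,
    "position": _norm_position,
    "region": _norm_region,
    "gene": str,
    "group": str,
    "source": str,
}


@dataclass(frozen=True)
class TypedInput:
    """A user-supplied list of one of the six data types.

    Items are normalized on construction (``rs`` prefixes stripped from SNP
    ids, coordinates coerced to ints) but duplicates and order are preserved,
    since annotation echoes the input row by row.
    """

    data_type: str
    items: tuple

    def __init__(self, data_type: str, items: Iterable):
        if data_type not in TYPES:
            raise KnowledgeError(f"unknown data type {data_type!r}")
        norm = _NORMALIZERS[data_type]
        object.__setattr__(self, "data_type", data_type)
        object.__setattr__(self, "items", tuple(norm(i) for i in items))
        if not self.items:
            raise KnowledgeError(f"empty {data_type} input")


# -- value formatting --------------------------------------------------------

_HEADERS = {
    "snp": ("snp",),
    "position": ("chr", "position"),
    "region": ("chr", "start", "end"),
    "gene": ("gene",),
    "group": ("group",),
    "source": ("source",),
}


def header_fields(types: Sequence[str]) -> tuple[str, ...]:
    return tuple(itertools.chain.from_iterable(_HEADERS[t] for t in types))


def format_entity(data_type: str, entity) -> tuple[str, ...]:
    """Printable TSV fields of one entity; blanks for a missing (None) one."""
    if entity is None:
        return ("",) * len(_HEADERS[data_type])
    if data_type == "snp":
        return (f"rs{entity}",)
    if data_type == "position":
        return (str(entity[0]), str(entity[1]))
    if data_type == "region":
        return (str(entity[0]), str(entity[1]), str(entity[2]))
    return (str(entity),)


def format_row(types: Sequence[str], row: Sequence) -> tuple[str, ...]:
    return tuple(
        itertools.chain.from_iterable(format_entity(t, e) for t, e in zip(types, row))
    )


# -- elementary mappings -----------------------------------------------------


def map_locus_to_genes(
    locus: tuple[str, int], store: KnowledgeStore, window: GeneWindow = GeneWindow()
) -> frozenset[str]:
    """Genes whose (window-extended) region contains the locus."""
    chrom, pos = _norm_position(locus)
    tree = store.region_index().get(chrom)
    if tree is None:
        return frozenset()
    w = window.flank_bp
    # tree intervals are [start, end+1); extend the query point by the flank
    hits = tree.overlap(pos - w, pos + w + 1)
    return frozenset(iv.data for iv in hits)


def _overlap_bases(region: tuple[str, int, int], start: int, end: int) -> int:
    lo = max(region[1], start)
    hi = min(region[2], end)
    return max(0, hi - lo + 1)


def map_region_to_genes(
    region: tuple[str, int, int],
    store: KnowledgeStore,
    policy: OverlapPolicy = OverlapPolicy(),
) -> frozenset[str]:
    """Genes a region maps to under the overlap policy."""
    chrom, start, end = _norm_region(region)
    tree = store.region_index().get(chrom)
    if tree is None:
        return frozenset()
    length = end - start + 1
    genes: set[str] = set()
    for iv in tree.overlap(start, end + 1):
        bases = _overlap_bases((chrom, start, end), iv.begin, iv.end - 1)
        if policy.kind == "bases":
            ok = bases >= policy.threshold
        else:
            ok = bases * 100 >= policy.threshold * length
        if ok:
            genes.add(iv.data)
    return frozenset(genes)


# -- the query context -------------------------------------------------------


class _QueryContext:
    """Precomputed link tables for one filter/annotate invocation."""

    def __init__(self, store, policy, window, overlap):
        self.store = store
        self.policy = policy
        self.window = window
        self.overlap = overlap
        self.group_list = store.group_ids()
        self.group_source = {g: store.group_source(g) for g in self.group_list}
        self.group_gene = {g: group_genes(store, g, policy) for g in self.group_list}
        self._locus_cache: dict = {}
        self._region_cache: dict = {}
        self._snp_cache: dict = {}

    def loci(self, rs: int) -> list[tuple[str, int]]:
        if rs not in self._snp_cache:
            self._snp_cache[rs] = self.store.snp_loci(rs)
        return self._snp_cache[rs]

    def genes_at(self, locus) -> frozenset[str]:
        if locus not in self._locus_cache:
            self._locus_cache[locus] = map_locus_to_genes(locus, self.store, self.window)
        return self._locus_cache[locus]

    def genes_of_region(self, region) -> frozenset[str]:
        if region not in self._region_cache:
            self._region_cache[region] = map_region_to_genes(
                region, self.store, self.overlap
            )
        return self._region_cache[region]

    def snp_genes(self, rs: int) -> frozenset[str]:
        out: set[str] = set()
        for locus in self.loci(rs):
            out |= self.genes_at(locus)
        return frozenset(out)

    def gene_groups(self, gene: str) -> frozenset[str]:
        return frozenset(g for g in self.group_list if gene in self.group_gene[g])

    def level2_genes(self, data_type: str, entity) -> frozenset[str]:
        """Genes standing in for an entity when joining through genes."""
        if data_type == "gene":
            return frozenset((entity,))
        if data_type == "region":
            return self.genes_of_region(entity)
        if data_type == "snp":
            return self.snp_genes(entity)
        if data_type == "position":
            return self.genes_at(entity)
        raise QueryError(f"cannot map {data_type} through genes")

    # one predicate per unordered type pair; (ta, ea) always at the lower or
    # equal chain level
    def linked(self, ta: str, ea, tb: str, eb) -> bool:
        if (LEVEL[ta], ta) > (LEVEL[tb], tb):
            ta, ea, tb, eb = tb, eb, ta, ea
        pair = (ta, tb)
        if pair == ("position", "snp"):
            return ea in self.loci(eb)
        if pair == ("snp", "gene"):
            return eb in self.snp_genes(ea)
        if pair == ("snp", "region"):
            return any(
                locus[0] == eb[0] and eb[1] <= locus[1] <= eb[2]
                for locus in self.loci(ea)
            )
        if pair == ("position", "gene"):
            return eb in self.genes_at(ea)
        if pair == ("position", "region"):
            return ea[0] == eb[0] and eb[1] <= ea[1] <= eb[2]
        if pair == ("gene", "region"):
            return ea in self.genes_of_region(eb)
        if tb == "group":
            return bool(self.level2_genes(ta, ea) & self.group_gene[eb])
        if pair == ("group", "source"):
            return self.group_source[ea] == eb
        if tb == "source":  # joined through genes and any group of the source
            genes = self.level2_genes(ta, ea)
            return any(
                self.group_source[g] == eb and genes & self.group_gene[g]
                for g in self.group_list
            )
        raise QueryError(f"unsupported type combination ({ta}, {tb})")


def _universe(ctx: _QueryContext, data_type: str, supplied: TypedInput | None,
              diagnostics: list[str] | None):
    """Entity universe for one type: the input items, or the whole store."""
    store = ctx.store
    if supplied is not None:
        if data_type == "snp":
            # normalize retired identifiers, keep first-seen order, dedupe
            return list(dict.fromkeys(store.current_rs(rs) for rs in supplied.items))
        if data_type == "gene":
            genes, warnings, _ = resolve_input_genes(supplied.items, store, ctx.policy)
            if diagnostics is not None:
                diagnostics.extend(warnings)
            return sorted(genes)
        if data_type == "group":
            groups, warnings, _ = resolve_input_groups(supplied.items, store, ctx.policy)
            if diagnostics is not None:
                diagnostics.extend(warnings)
            return sorted(groups)
        if data_type == "source":
            known = store.sources()
            out = []
            for name in dict.fromkeys(supplied.items):
                if name in known:
                    out.append(name)
                elif diagnostics is not None:
                    diagnostics.append(f"unknown source name {name!r}")
            return out
        return list(dict.fromkeys(supplied.items))
    if data_type == "snp":
        return sorted(store.snp_ids())
    if data_type == "position":
        return sorted(
            {(c, p) for _, c, p in store.all_loci()},
            key=lambda cp: (chromosome_key(cp[0]), cp[1]),
        )
    if data_type == "region":
        return sorted(
            {(c, s, e) for c, s, e, _ in store.all_regions()},
            key=lambda r: (chromosome_key(r[0]), r[1], r[2]),
        )
    if data_type == "gene":
        return sorted(store.gene_ids())
    if data_type == "group":
        return list(ctx.group_list)
    if data_type == "source":
        return sorted(store.sources())
    raise QueryError(f"unknown data type {data_type!r}")


def _required_pairs(involved: Sequence[str]) -> set[frozenset[str]]:
    """Type pairs whose link must hold: same level, or adjacent present levels."""
    levels = sorted({LEVEL[t] for t in involved})
    adjacent = {frozenset(levels[i : i + 2]) for i in range(len(levels) - 1)}
    pairs: set[frozenset[str]] = set()
    for ta, tb in itertools.combinations(involved, 2):
        la, lb = LEVEL[ta], LEVEL[tb]
        if la == lb or frozenset((la, lb)) in adjacent:
            pairs.add(frozenset((ta, tb)))
    return pairs


def filter_query(
    inputs: Sequence[TypedInput],
    output_types: Sequence[str],
    store: KnowledgeStore,
    policy: AmbiguityPolicy = AmbiguityPolicy(),
    window: GeneWindow = GeneWindow(),
    overlap: OverlapPolicy = OverlapPolicy(),
    diagnostics: list[str] | None = None,
) -> list[tuple]:
    """All connected entity tuples over ``output_types``.

    A type carrying a supplied input is restricted to that input's items; a
    requested type with no input ranges over the whole store.  Input types
    not among the output types still constrain the result (they participate
    in the join and are projected away).  Rows are deduplicated and sorted by
    their printed fields.
    """
    output_types = tuple(output_types)
    if not output_types:
        raise QueryError("at least one output type is required")
    for t in output_types:
        if t not in TYPES:
            raise QueryError(f"unknown data type {t!r}")
    if len(set(output_types)) != len(output_types):
        raise QueryError("duplicate output types are not supported")

    by_type: dict[str, TypedInput] = {}
    for inp in inputs:
        if inp.data_type in by_type:
            raise QueryError(f"duplicate {inp.data_type} input")
        by_type[inp.data_type] = inp

    ctx = _QueryContext(store, policy, window, overlap)
    involved = sorted(set(output_types) | set(by_type), key=lambda t: (LEVEL[t], t))
    universes = {
        t: _universe(ctx, t, by_type.get(t), diagnostics) for t in involved
    }
    required = _required_pairs(involved)

    results: set[tuple] = set()

    def extend(idx: int, assignment: dict):
        if idx == len(involved):
            results.add(tuple(assignment[t] for t in output_types))
            return
        t = involved[idx]
        for entity in universes[t]:
            ok = True
            for prev in involved[:idx]:
                if frozenset((prev, t)) in required and not ctx.linked(
                    prev, assignment[prev], t, entity
                ):
                    ok = False
                    break
            if ok:
                assignment[t] = entity
                extend(idx + 1, assignment)
                del assignment[t]

    extend(0, {})
    return sorted(results, key=lambda row: format_row(output_types, row))


def annotate_query(
    primary: TypedInput,
    annotation_types: Sequence[str],
    store: KnowledgeStore,
    policy: AmbiguityPolicy = AmbiguityPolicy(),
    window: GeneWindow = GeneWindow(),
    overlap: OverlapPolicy = OverlapPolicy(),
    extra_inputs: Sequence[TypedInput] = (),
    diagnostics: list[str] | None = None,
) -> list[tuple]:
    """Annotate each primary item with connected entities of the given types.

    Items are processed in input order; an item with several matches is
    repeated once per match, and an item with none appears exactly once with
    ``None`` in every annotation slot (rendered as blank columns).  Extra
    inputs of other types further constrain which matches qualify, so
    annotation of a filtered set is the same call with those inputs attached.
    """
    annotation_types = tuple(annotation_types)
    for t in annotation_types:
        if t == primary.data_type:
            raise QueryError("annotation types must differ from the primary type")
    rows: list[tuple] = []
    for item in primary.items:
        single = TypedInput(primary.data_type, [item])
        sub = filter_query(
            [single, *extra_inputs],
            (primary.data_type, *annotation_types),
            store,
            policy,
            window,
            overlap,
            diagnostics=diagnostics,
        )
        if sub:
            rows.extend(sub)
        else:
            echoed = single.items[0]
            if primary.data_type == "snp":
                echoed = store.current_rs(echoed)
            rows.append((echoed,) + (None,) * len(annotation_types))
    return rows
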