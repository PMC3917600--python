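"""Locus/region-to-gene mapping and the filter/annotate query modes."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from knowfilter.ambiguity import AmbiguityPolicy
from knowfilter.engine import (
    GeneWindow,
    OverlapPolicy,
    TypedInput,
    annotate_query,
    filter_query,
    format_row,
    map_locus_to_genes,
    map_region_to_genes,
)
from knowfilter.errors import QueryError
from knowfilter.simulate import CHR1_SNPS

from conftest import make_store, random_store_text


class TestLocusMapping:
    def test_snp_in_two_overlapping_genes(self, sim_store):
        locus = sim_store.snp_loci(24)[0]
        assert map_locus_to_genes(locus, sim_store) == {"H", "I"}

    def test_window_extends_gene_boundaries(self, sim_store):
        # gene C starts at 1:3000; one bp to the left is outside at window 0
        assert map_locus_to_genes(("1", 2999), sim_store) == frozenset()
        assert map_locus_to_genes(("1", 2999), sim_store, GeneWindow(1)) == {"C"}

    def test_intergenic_locus_maps_nowhere(self, sim_store):
        assert map_locus_to_genes(("1", 2500), sim_store) == frozenset()

    def test_window_monotonicity(self, sim_store):
        for _, chrom, pos in sim_store.all_loci():
            previous = frozenset()
            for flank in (0, 100, 1000, 10000):
                genes = map_locus_to_genes((chrom, pos), sim_store, GeneWindow(flank))
                assert previous <= genes
                previous = genes


class TestRegionMapping:
    def test_single_base_overlap_suffices_by_default(self, sim_store):
        # gene H spans 2:9000-10000; this region touches only its first base
        assert map_region_to_genes(("2", 8500, 9000), sim_store) == {"H"}

    def test_base_threshold_excludes_small_overlap(self, sim_store):
        policy = OverlapPolicy("bases", 2)
        assert map_region_to_genes(("2", 8500, 9000), sim_store, policy) == frozenset()

    def test_full_percent_overlap_of_identical_region(self, sim_store):
        policy = OverlapPolicy("percent", 100)
        assert map_region_to_genes(("1", 1000, 2000), sim_store, policy) == {"A"}

    def test_percent_is_measured_against_input_region(self, sim_store):
        # 1000 of this 2000-bp region overlap gene A: 50% but not 51%
        region = ("1", 1001, 3000)
        assert "A" in map_region_to_genes(region, sim_store, OverlapPolicy("percent", 50))
        assert "A" not in map_region_to_genes(region, sim_store, OverlapPolicy("percent", 51))

    def test_threshold_monotonicity(self, sim_store):
        region = ("2", 9400, 10100)
        previous = None
        for threshold in (1, 10, 100, 1000):
            genes = map_region_to_genes(region, sim_store, OverlapPolicy("bases", threshold))
            if previous is not None:
                assert genes <= previous
            previous = genes


class TestFilter:
    def test_snp_list_filtered_by_gene_list(self, sim_store):
        rows = filter_query(
            [TypedInput("snp", CHR1_SNPS), TypedInput("gene", ["A", "C"])],
            ("snp",),
            sim_store,
        )
        assert rows == [(11,), (12,), (15,), (16,)]

    def test_all_genes_of_a_source(self, sim_store):
        rows = filter_query([TypedInput("source", ["light"])], ("gene",), sim_store)
        assert rows == [("A",), ("B",), ("C",), ("E",), ("F",)]

    def test_snp_gene_pair_output(self, sim_store):
        rows = filter_query(
            [TypedInput("snp", CHR1_SNPS), TypedInput("gene", ["A", "C"])],
            ("snp", "gene"),
            sim_store,
        )
        assert rows == [(11, "A"), (12, "A"), (15, "C"), (16, "C")]

    def test_unconstrained_type_ranges_over_whole_store(self, sim_store):
        # genes constrained only through the source and group chain
        rows = filter_query(
            [TypedInput("group", ["orange"])], ("gene",), sim_store
        )
        assert rows == [("H",), ("I",)]

    def test_cross_chain_join_through_genes(self, sim_store):
        # SNPs and groups supplied, genes requested: genes holding at least
        # one input SNP and belonging to at least one input group
        rows = filter_query(
            [TypedInput("snp", ["rs24", "rs31"]), TypedInput("group", ["orange"])],
            ("gene",),
            sim_store,
        )
        assert rows == [("H",), ("I",)]

    def test_retired_rs_is_normalized_before_matching(self, sim_store):
        rows = filter_query(
            [TypedInput("snp", ["rs90"]), TypedInput("gene", ["H"])],
            ("snp",),
            sim_store,
        )
        assert rows == [(24,)]

    def test_input_order_is_irrelevant(self, sim_store):
        inputs = [
            TypedInput("snp", CHR1_SNPS),
            TypedInput("gene", ["A", "C"]),
            TypedInput("source", ["light", "paint"]),
        ]
        expected = filter_query(inputs, ("snp", "gene"), sim_store)
        for permutation in itertools.permutations(inputs):
            assert filter_query(list(permutation), ("snp", "gene"), sim_store) == expected

    @pytest.mark.parametrize(
        "extra",
        [
            TypedInput("gene", ["A"]),
            TypedInput("group", ["blue"]),
            TypedInput("source", ["light"]),
            TypedInput("position", [("1", 1100)]),
        ],
    )
    def test_adding_an_input_never_adds_rows(self, sim_store, extra):
        base = [TypedInput("snp", CHR1_SNPS)]
        before = set(filter_query(base, ("snp", "gene"), sim_store))
        after = set(filter_query(base + [extra], ("snp", "gene"), sim_store))
        assert after <= before

    def test_duplicate_output_types_rejected(self, sim_store):
        with pytest.raises(QueryError):
            filter_query([], ("gene", "gene"), sim_store)

    def test_rows_are_sorted_by_printed_fields(self, sim_store):
        rows = filter_query([], ("group", "source"), sim_store)
        printed = [format_row(("group", "source"), r) for r in rows]
        assert printed == sorted(printed)


class TestAnnotate:
    def test_unknown_snp_gets_blank_columns(self, sim_store):
        rows = annotate_query(
            TypedInput("snp", ["rs11", "rs99"]), ("position",), sim_store
        )
        assert rows == [(11, ("1", 1100)), (99, None)]

    def test_multigene_snp_repeated_per_gene(self, sim_store):
        rows = annotate_query(TypedInput("snp", ["rs24"]), ("gene",), sim_store)
        assert rows == [(24, "H"), (24, "I")]

    def test_multilocus_snp_repeated_per_position(self, sim_store):
        rows = annotate_query(TypedInput("snp", ["rs30"]), ("position",), sim_store)
        assert rows == [(30, ("2", 6500)), (30, ("3", 2500))]

    def test_gene_list_annotated_with_regions(self, sim_store):
        rows = annotate_query(TypedInput("gene", ["M", "A"]), ("region",), sim_store)
        assert rows == [
            ("M", ("3", 7000, 8000)),
            ("M", ("3", 9000, 9500)),
            ("A", ("1", 1000, 2000)),
        ]

    def test_input_order_is_preserved(self, sim_store):
        rows = annotate_query(
            TypedInput("snp", ["rs16", "rs11"]), ("gene",), sim_store
        )
        assert rows == [(16, "C"), (11, "A")]

    def test_every_primary_item_appears(self, sim_store):
        items = ["rs11", "rs99", "rs24", "rs13"]
        rows = annotate_query(TypedInput("snp", items), ("gene",), sim_store)
        assert len(rows) >= len(items)
        assert [r[0] for r in rows if r[0] in (11, 99, 13)] == [11, 99, 13]

    def test_nonblank_rows_match_filter_output(self, sim_store):
        primary = TypedInput("snp", [f"rs{r}" for r in sorted(sim_store.snp_ids())])
        annotated = annotate_query(primary, ("gene",), sim_store)
        nonblank = {r for r in annotated if r[1] is not None}
        filtered = set(filter_query([primary], ("snp", "gene"), sim_store))
        assert nonblank == filtered

    def test_extra_inputs_constrain_annotation(self, sim_store):
        rows = annotate_query(
            TypedInput("snp", ["rs24"]),
            ("gene",),
            sim_store,
            extra_inputs=[TypedInput("gene", ["H"])],
        )
        assert rows == [(24, "H")]


def oracle_pairs(store, policy, window_bp=0):
    """Independent exhaustive enumerator for (snp, gene) and (gene, group)."""
    snp_gene = set()
    for rs in store.snp_ids():
        for chrom, pos in store.snp_loci(rs):
            for rchrom, start, end, gene in store.all_regions():
                if chrom == rchrom and start - window_bp <= pos <= end + window_bp:
                    snp_gene.add((rs, gene))
    gene_group = set()
    for gid in store.group_ids():
        resolved = set()
        for member in store.group_members(gid):
            from knowfilter.ambiguity import resolve_member

            outcome, _ = resolve_member(member, store, policy)
            resolved |= outcome
        gene_group.update((g, gid) for g in resolved)
    return snp_gene, gene_group


class TestOracleEquivalence:
    @given(text=random_store_text())
    def test_filter_matches_exhaustive_enumeration(self, text):
        store = make_store(text)
        policy = AmbiguityPolicy("none", "permissive")
        snp_gene, gene_group = oracle_pairs(store, policy)

        got = set(filter_query([], ("snp", "gene"), store, policy))
        assert got == snp_gene

        got = set(filter_query([], ("gene", "group"), store, policy))
        assert got == gene_group

        # cross-chain: snp-group joined through any shared gene
        expected = {
            (rs, gid)
            for (rs, g1) in snp_gene
            for (g2, gid) in gene_group
            if g1 == g2
        }
        got = set(filter_query([], ("snp", "group"), store, policy))
        assert got == expected

        # three-way tuples chain snp-gene and gene-group links
        expected3 = {
            (rs, g, gid)
            for (rs, g) in snp_gene
            for (g2, gid) in gene_group
            if g == g2
        }
        got = set(filter_query([], ("snp", "gene", "group"), store, policy))
        assert got == expected3
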