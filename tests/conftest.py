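"""Shared fixtures: the simulated knowledge store and randomized tiny stores."""

import tempfile
from pathlib import Path

import pytest
from hypothesis import settings
from hypothesis import strategies as st

from knowfilter.simulate import load_simulated_store
from knowfilter.store import ingest_knowledge

settings.register_profile("default", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_store():
    """The bundled simulated knowledge base, ingested once per session."""
    return load_simulated_store()


def make_store(text: str):
    """Ingest a knowledge-definition blob into a fresh in-memory store."""
    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "kb.txt"
        path.write_text(text, encoding="utf-8")
        return ingest_knowledge([path])


@st.composite
def random_store_text(draw):
    """A small random but internally consistent knowledge bundle.

    Two sources, up to four groups, up to six genes on two chromosomes with
    possibly overlapping regions, ambiguous symbol and protein aliases, and a
    handful of SNPs — enough structure to exercise every resolution and join
    path while staying exhaustively checkable by brute force.
    """
    n_genes = draw(st.integers(2, 6))
    genes = [f"G{i}" for i in range(n_genes)]
    lines = ["build\trand", "source\tS1", "source\tS2"]
    for i, g in enumerate(genes):
        chrom = draw(st.integers(1, 2))
        start = draw(st.integers(1, 40)) * 500 + 1
        end = start + draw(st.integers(100, 3000))
        lines.append(f"gene\t{g}\t{g}\t{chrom} {start} {end}")

    gene_subsets = st.sets(st.sampled_from(genes), min_size=1, max_size=min(3, n_genes))
    alias_names = []
    for j in range(draw(st.integers(0, 3))):
        targets = sorted(draw(gene_subsets))
        lines.append(f"alias\tX{j}\tsymbol\t{','.join(targets)}")
        alias_names.append(("X" + str(j), "symbol"))
    protein_names = []
    for j in range(draw(st.integers(0, 3))):
        targets = sorted(draw(gene_subsets))
        lines.append(f"alias\tP{j}\tprotein\t{','.join(targets)}")
        protein_names.append(("P" + str(j), "protein"))

    n_snps = draw(st.integers(0, 6))
    for rs in range(1, n_snps + 1):
        chrom = draw(st.integers(1, 2))
        pos = draw(st.integers(1, 25000))
        lines.append(f"snp\t{rs}\t{chrom}\t{pos}")

    identifier_pool = (
        [(g, "symbol") for g in genes] + alias_names + protein_names
    )
    n_groups = draw(st.integers(1, 4))
    for k in range(n_groups):
        source = "S1" if k % 2 == 0 else "S2"
        lines.append(f"group\t{source}\tgrp{k}\tgrp{k}")
        for _ in range(draw(st.integers(1, 3))):
            idents = draw(
                st.sets(st.sampled_from(identifier_pool), min_size=1, max_size=3)
            )
            spec = ",".join(f"{n}:{t}" for n, t in sorted(idents))
            lines.append(f"member\tgrp{k}\t{spec}")
    return "\n".join(lines) + "\n"
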