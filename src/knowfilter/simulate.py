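"""The bundled simulated knowledge database and its worked examples.

Real prior-knowledge stores are large and change under the user's feet, so
the package ships a small, frozen, entirely synthetic knowledge base for
learning the tool and for regression testing.  It contains three fictitious
sources (``light``, ``paint``, ``spectrum``), eleven groups (two of which
share the name ``gray`` while also carrying the distinct names ``white`` and
``black``), thirteen single-letter genes ``A``..``M`` on three chromosomes,
and twenty-one SNPs, plus deliberately ambiguous aliases (``DE`` names both
``D`` and ``E``), protein identifiers, a multi-region gene and one retired
rs number.

Everything here is generated from literal tables with no randomness, so
rebuilding the bundle is byte-identical; the pre-built copy shipped under
``knowfilter/data/`` must always equal :func:`simulated_kb_text` output.

Key fixed facts exercised by the worked examples:

* chromosome 1 carries genes ``A``, ``C`` and ``F``; ``A`` contains rs11 and
  rs12, ``C`` contains rs15 and rs16, ``F`` contains no SNPs;
* ``A`` and ``C`` co-occur in exactly the groups ``blue``, ``gray/white``
  and ``cyan``, owned by the two sources ``light`` and ``paint`` — the
  implication index of the pair is ``2-3``;
* rs24 lies inside both overlapping genes ``H`` and ``I``; rs99 does not
  exist in the store; retired rs90 merges to rs24.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .errors import KnowledgeError
from .store import KnowledgeStore, ingest_knowledge

BUILD_LABEL = "simB1"
BUNDLE_NAME = "simulated_kb.txt"

_GENES = [
    # gene_id, symbol, regions "chrom start end[;...]"
    ("A", "A", "1 1000 2000"),
    ("B", "B", "2 1000 2000"),
    ("C", "C", "1 3000 4000"),
    ("D", "D", "2 3000 4000"),
    ("E", "E", "2 5000 6000"),
    ("F", "F", "1 5000 6000"),
    ("G", "G", "2 7000 8000"),
    ("H", "H", "2 9000 10000"),
    ("I", "I", "2 9500 10500"),
    ("J", "J", "3 1000 2000"),
    ("K", "K", "3 3000 4000"),
    ("L", "L", "3 5000 6000"),
    ("M", "M", "3 7000 8000;3 9000 9500"),  # multi-region gene
]

_ALIASES = [
    # extra names beyond each gene's own symbol; (name, id_type, targets)
    ("DE", "symbol", "D,E"),      # ambiguous: names two genes
    ("Galt", "symbol", "G"),
    ("GH", "symbol", "G,H"),
    ("Jalt", "symbol", "J"),
    ("JK", "symbol", "J,K"),
    ("Lalt", "symbol", "L"),
    ("LM", "symbol", "L,M"),
    ("101", "numeric", "A"),
    ("103", "numeric", "C"),
    ("104", "numeric", "D"),
    ("p1", "protein", "D,E"),     # proteins legitimately map to many genes
    ("p2", "protein", "H,I"),
    ("p3", "protein", "I,J"),
]

_SNPS = [
    # rs, chrom, pos  (rs30 has two loci; rs13/28/36 are intergenic)
    (11, "1", 1100),
    (12, "1", 1500),
    (13, "1", 2500),
    (15, "1", 3200),
    (16, "1", 3900),
    (21, "2", 1500),
    (22, "2", 3500),
    (23, "2", 5500),
    (24, "2", 9800),
    (25, "2", 7500),
    (26, "2", 9200),
    (27, "2", 10200),
    (28, "2", 12000),
    (29, "2", 3600),
    (30, "2", 6500),
    (30, "3", 2500),
    (31, "3", 1500),
    (32, "3", 3500),
    (33, "3", 5500),
    (34, "3", 7500),
    (35, "3", 9200),
    (36, "3", 12000),
]

_MERGES = [(90, 24)]

_GROUPS = [
    # source, group_id, names, members (each member = identifier spec string)
    ("light", "red", "red", ["F:symbol", "B:symbol"]),
    ("light", "green", "green", ["B:symbol", "E:symbol"]),
    ("light", "blue", "blue", ["A:symbol", "C:symbol"]),
    ("paint", "gray_white", "gray|white", ["A:symbol", "C:symbol", "D:symbol"]),
    ("paint", "cyan", "cyan", ["A:symbol", "C:symbol", "D:symbol,DE:symbol"]),
    ("paint", "magenta", "magenta", ["G:symbol,Galt:symbol,GH:symbol"]),
    ("paint", "yellow", "yellow", ["J:symbol,Jalt:symbol,JK:symbol"]),
    ("spectrum", "gray_black", "gray|black", ["L:symbol,Lalt:symbol,LM:symbol"]),
    ("spectrum", "orange", "orange", ["H:symbol", "I:symbol"]),
    ("spectrum", "indigo", "indigo", ["p1:protein,D:symbol", "K:symbol"]),
    ("spectrum", "violet", "violet", ["p2:protein,p3:protein", "M:symbol"]),
]


def simulated_kb_text() -> str:
    """The complete knowledge-definition bundle as a single text blob."""
    lines = [
        "# simulated knowledge database (synthetic) for exploring knowfilter",
        f"build\t{BUILD_LABEL}",
    ]
    for source in ("light", "paint", "spectrum"):
        lines.append(f"source\t{source}")
    for gene_id, symbol, regions in _GENES:
        lines.append(f"gene\t{gene_id}\t{symbol}\t{regions}")
    for name, id_type, targets in _ALIASES:
        lines.append(f"alias\t{name}\t{id_type}\t{targets}")
    for rs, chrom, pos in _SNPS:
        lines.append(f"snp\t{rs}\t{chrom}\t{pos}")
    for old, new in _MERGES:
        lines.append(f"merge\t{old}\t{new}")
    for source, group_id, names, members in _GROUPS:
        lines.append(f"group\t{source}\t{group_id}\t{names}")
        for member in members:
            lines.append(f"member\t{group_id}\t{member}")
    return "\n".join(lines) + "\n"


def build_simulated_kb(output_dir: str | Path) -> Path:
    """Write the bundle into ``output_dir`` and return the file path."""
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        path = out / BUNDLE_NAME
        path.write_text(simulated_kb_text(), encoding="utf-8")
    except OSError as exc:
        raise KnowledgeError(f"cannot write simulated knowledge bundle: {exc}")
    return path


def packaged_kb_path() -> Path:
    """Path of the pre-built bundle shipped inside the package."""
    return Path(importlib.resources.files("knowfilter") / "data" / BUNDLE_NAME)


def load_simulated_store(db_path=None) -> KnowledgeStore:
    """Ingest the packaged bundle into a fresh (by default in-memory) store."""
    return ingest_knowledge([packaged_kb_path()], db_path=db_path)


# -- canonical worked examples ----------------------------------------------

CHR1_SNPS = ["rs11", "rs12", "rs13", "rs15", "rs16"]


@dataclass(frozen=True)
class CanonicalExample:
    """Frozen inputs plus expected printed rows for one worked example."""

    name: str
    mode: str                       # filter | annotate | model
    inputs: dict                    # data_type -> list of raw input values
    output_types: tuple = ()        # filter/annotate column types
    model_type: str = ""            # model mode only
    expected_rows: tuple = ()       # printed TSV field tuples, in output order
    expected_gene_models: tuple = ()  # model mode: (gene_a, gene_b, index)


_EXAMPLES = {
    # all genes reachable from the source "light"
    "fig5_source_genes": CanonicalExample(
        name="fig5_source_genes",
        mode="filter",
        inputs={"source": ["light"]},
        output_types=("gene",),
        expected_rows=(("A",), ("B",), ("C",), ("E",), ("F",)),
    ),
    # filtering the chromosome-1 SNP list by the gene list {A, C}
    "fig6_filter": CanonicalExample(
        name="fig6_filter",
        mode="filter",
        inputs={"snp": CHR1_SNPS, "gene": ["A", "C"]},
        output_types=("snp",),
        expected_rows=(("rs11",), ("rs12",), ("rs15",), ("rs16",)),
    ),
    # annotating a SNP list with genes: rs24 is in two genes, rs99 in none
    "fig7_annotate": CanonicalExample(
        name="fig7_annotate",
        mode="annotate",
        inputs={"snp": ["rs11", "rs24", "rs99"]},
        output_types=("snp", "gene"),
        expected_rows=(("rs11", "A"), ("rs24", "H"), ("rs24", "I"), ("rs99", "")),
    ),
    # modeling from the chromosome-1 SNP list: single gene model (A, C) "2-3"
    "fig9_models": CanonicalExample(
        name="fig9_models",
        mode="model",
        inputs={"snp": CHR1_SNPS},
        model_type="snp",
        expected_gene_models=(("A", "C", "2-3"),),
        expected_rows=(
            ("rs11", "rs15", "2-3", "2", "3"),
            ("rs11", "rs16", "2-3", "2", "3"),
            ("rs12", "rs15", "2-3", "2", "3"),
            ("rs12", "rs16", "2-3", "2", "3"),
        ),
    ),
}


def canonical_example(name: str, output_dir: str | Path | None = None):
    """Return a frozen worked example; optionally write its input files.

    With ``output_dir`` set, each input list is written as a one-value-per-
    line file and the expected output as ``expected.tsv``; the returned
    mapping of paths is attached for convenience.
    """
    if name not in _EXAMPLES:
        raise KnowledgeError(
            f"unknown example {name!r}; valid names: {', '.join(sorted(_EXAMPLES))}"
        )
    example = _EXAMPLES[name]
    if output_dir is None:
        return example
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for data_type, values in example.inputs.items():
        path = out / f"{example.name}.{data_type}.txt"
        path.write_text("\n".join(str(v) for v in values) + "\n", encoding="utf-8")
        paths[data_type] = path
    expected = out / f"{example.name}.expected.tsv"
    expected.write_text(
        "\n".join("\t".join(row) for row in example.expected_rows) + "\n",
        encoding="utf-8",
    )
    return example, paths, expected
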