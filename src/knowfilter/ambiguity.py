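"""Resolution of ambiguous gene, group and protein identifiers.

A knowledge source frequently names one group member with several identifiers
(a symbol plus a numeric id, say), and a single name can point at more than
one gene.  This module turns such identifier bundles into concrete gene sets
under a user-selected :class:`AmbiguityPolicy`:

* ``mode='strict'`` drops a member entirely whenever more than one gene
  survives (no false positives, possible false negatives);
* ``mode='permissive'`` keeps every surviving candidate;
* the ``implication`` heuristic prefers the gene implicated by the largest
  number of the member's identifiers;
* the ``quality`` heuristic additionally down-weights promiscuous
  identifiers: each identifier contributes ``1/|targets|`` to every gene it
  names, so a name pointing at a single gene outweighs one pointing at many;
* ``any`` takes the union of the winners of both heuristics.

Protein identifiers get special treatment: because one protein legitimately
maps to several genes, the presence of any protein identifier in a member
makes the non-protein identifiers irrelevant, and identifier "quality" loses
its meaning — implication and quality then coincide by construction.

Quality scores are kept as exact :class:`fractions.Fraction` values so that
argmax ties are decided exactly, never by floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import KnowledgeError
from .store import GroupMember, KnowledgeStore

HEURISTICS = ("none", "implication", "quality", "any")
MODES = ("strict", "permissive")

#: dispositions recorded in a ResolutionReport
UNAMBIGUOUS = "unambiguous"
HEURISTIC_RESOLVED = "heuristic_resolved"
DROPPED_STRICT = "dropped_strict"
INCLUDED_ALL_PERMISSIVE = "included_all_permissive"


@dataclass(frozen=True)
class AmbiguityPolicy:
    """How ambiguity in knowledge groups and input lists is interpreted.

    Defaults are the conservative ones: no heuristic, strict mode, ambiguous
    input names dropped.
    """

    heuristic: str = "none"
    mode: str = "strict"
    allow_ambiguous_genes: bool = False
    allow_ambiguous_groups: bool = False

    def __post_init__(self):
        if self.heuristic not in HEURISTICS:
            raise KnowledgeError(f"unknown heuristic {self.heuristic!r}")
        if self.mode not in MODES:
            raise KnowledgeError(f"unknown ambiguity mode {self.mode!r}")


@dataclass
class ResolutionReport:
    """Audit record of one resolution decision."""

    item: str
    candidates: dict
    outcome: frozenset[str]
    disposition: str

    def tsv_fields(self) -> tuple[str, str, str, str]:
        cand = ",".join(sorted(self.candidates))
        scores = ",".join(
            f"{g}={_fmt_score(self.candidates[g])}" for g in sorted(self.candidates)
        )
        return (self.item, cand, scores, self.disposition)


def _fmt_score(v) -> str:
    if isinstance(v, Fraction):
        return str(float(v)) if v.denominator != 1 else str(v.numerator)
    return str(v)


def candidate_genes(member: GroupMember, store: KnowledgeStore) -> dict[str, int]:
    """Candidate genes of a member with their implication supports.

    If the member carries any protein identifier, non-protein identifiers are
    disregarded and candidates are the union of the protein identifiers'
    genes; otherwise candidates come from the gene-type identifiers.  The
    support of a gene is the number of (retained) identifiers naming it.
    Identifiers unknown to the store contribute nothing.
    """
    protein_ids = [(n, t) for n, t in member.identifiers if t == "protein"]
    use = protein_ids if protein_ids else sorted(member.identifiers)
    support: dict[str, int] = {}
    for name, id_type in use:
        for gene in store.genes_by_name(name, id_type):
            support[gene] = support.get(gene, 0) + 1
    return support


def quality_scores(member: GroupMember, store: KnowledgeStore) -> dict[str, Fraction]:
    """Quality-weighted supports: each identifier splits a unit weight evenly
    over the genes it names, so low-ambiguity identifiers weigh more.

    Defined for members without protein identifiers; with proteins involved
    the quality notion collapses onto plain implication counts, and callers
    should use :func:`candidate_genes` instead.
    """
    if any(t == "protein" for _, t in member.identifiers):
        raise KnowledgeError("quality scores are undefined for protein identifiers")
    score: dict[str, Fraction] = {}
    for name, id_type in sorted(member.identifiers):
        targets = store.genes_by_name(name, id_type)
        if not targets:
            continue
        w = Fraction(1, len(targets))
        for gene in targets:
            score[gene] = score.get(gene, Fraction(0)) + w
    return score


def _argmax(scores: Mapping[str, object]) -> frozenset[str]:
    if not scores:
        return frozenset()
    best = max(scores.values())
    return frozenset(g for g, s in scores.items() if s == best)


def resolve_member(
    member: GroupMember, store: KnowledgeStore, policy: AmbiguityPolicy
) -> tuple[frozenset[str], ResolutionReport]:
    """Resolve one group member to its included gene set under ``policy``.

    The heuristic (if any) first narrows the candidate set to its winners;
    a single survivor is always included, multiple survivors are all included
    under permissive mode and dropped entirely under strict mode.
    """
    counts = candidate_genes(member, store)
    has_protein = any(t == "protein" for _, t in member.identifiers)

    if policy.heuristic == "none":
        winners = frozenset(counts)
    elif policy.heuristic == "implication":
        winners = _argmax(counts)
    elif policy.heuristic == "quality":
        winners = _argmax(counts if has_protein else quality_scores(member, store))
    else:  # any: union of the winners of both heuristics
        q = counts if has_protein else quality_scores(member, store)
        winners = _argmax(counts) | _argmax(q)

    if len(winners) == 1:
        outcome = winners
        disposition = UNAMBIGUOUS if len(counts) == 1 else HEURISTIC_RESOLVED
    elif policy.mode == "permissive":
        outcome = winners
        disposition = INCLUDED_ALL_PERMISSIVE
    else:
        outcome = frozenset()
        disposition = DROPPED_STRICT

    report = ResolutionReport(
        item=member.ident_key, candidates=dict(counts), outcome=outcome,
        disposition=disposition,
    )
    return outcome, report


def group_genes(
    store: KnowledgeStore, group_id: str, policy: AmbiguityPolicy
) -> frozenset[str]:
    """Resolved gene membership of a group: union over its members."""
    genes: set[str] = set()
    for member in store.group_members(group_id):
        outcome, _ = resolve_member(member, store, policy)
        genes |= outcome
    return frozenset(genes)


def _resolve_names(
    names: Iterable[str],
    lookup,
    allow_ambiguous: bool,
    what: str,
) -> tuple[frozenset[str], list[str], list[ResolutionReport]]:
    included: set[str] = set()
    warnings: list[str] = []
    reports: list[ResolutionReport] = []
    for name in names:
        targets = lookup(name)
        if len(targets) == 1:
            included |= targets
            continue
        if not targets:
            warnings.append(f"unknown {what} name {name!r}: no match in the knowledge store")
            reports.append(ResolutionReport(name, {}, frozenset(), DROPPED_STRICT))
            continue
        if allow_ambiguous:
            included |= targets
            outcome, disposition = frozenset(targets), INCLUDED_ALL_PERMISSIVE
            warnings.append(
                f"ambiguous {what} name {name!r} matches {len(targets)}; all included"
            )
        else:
            outcome, disposition = frozenset(), DROPPED_STRICT
            warnings.append(
                f"ambiguous {what} name {name!r} matches {len(targets)}; all dropped"
            )
        reports.append(
            ResolutionReport(name, {t: 1 for t in targets}, outcome, disposition)
        )
    return frozenset(included), warnings, reports


def resolve_input_genes(
    names: Sequence[str], store: KnowledgeStore, policy: AmbiguityPolicy
) -> tuple[frozenset[str], list[str], list[ResolutionReport]]:
    """Resolve user-supplied gene names to gene ids.

    Unambiguous names map to their gene; ambiguous names contribute all their
    targets when ``allow_ambiguous_genes`` is set and nothing otherwise, with
    a warning either way; unknown names contribute nothing and warn.
    """
    return _resolve_names(
        names, store.genes_by_name, policy.allow_ambiguous_genes, "gene"
    )


def resolve_input_groups(
    names: Sequence[str], store: KnowledgeStore, policy: AmbiguityPolicy
) -> tuple[frozenset[str], list[str], list[ResolutionReport]]:
    """Resolve user-supplied group names to group ids (symmetric to genes)."""
    return _resolve_names(
        names, store.groups_by_name, policy.allow_ambiguous_groups, "group"
    )


def write_resolution_report(path, reports: Iterable[ResolutionReport]) -> None:
    """Write the detailed ambiguity report as a four-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("item\tcandidates\tscores\tdisposition\n")
        for report in reports:
            fh.write("\t".join(report.tsv_fields()) + "\n")
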