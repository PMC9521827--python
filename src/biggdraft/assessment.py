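"""Scoring drafts against reference models and multi-model overlap summaries.

A draft is compared to a curated reference on the identifier sets of their
*comparable* reactions — all reactions except exchange, sink and demand
pseudo-reactions.  Reactions present in both are true positives (TP), in the
draft only false positives (FP), in the reference only false negatives (FN),
and the usual precision / recall / F1 follow:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R).

Multi-model content comparisons are provided as exact Venn-region counts
(:func:`overlap_regions`) and as a PCA over binary content matrices
(:func:`model_content_pca`), for reactions, metabolites or COG annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .integration import BOUNDARY_PREFIXES
from .template_selection import PcaResult, pca_profiles

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricTriple",
    "comparable_reaction_set",
    "confusion",
    "metrics",
    "format_report",
    "overlap_regions",
    "feature_sets",
    "model_content_pca",
]

_COPY_SUFFIX = re.compile(r"_copy\d+$")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN of a draft reaction set against a reference reaction set."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricTriple:
    """Precision, recall and F1; ``degenerate`` marks a zero denominator
    (the affected metric is reported as 0 rather than raising)."""

    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def _reactions_of(model) -> Iterable:
    reactions = getattr(model, "reactions", model)
    if isinstance(reactions, dict):
        return reactions.values()
    return reactions


def comparable_reaction_set(
    model, strip_copy_suffix: bool = False, by_stoichiometry: bool = False
) -> Set[str]:
    """Reaction identifiers retained for draft-vs-reference comparison.

    Excludes boundary pseudo-reactions, identified either by their id prefix
    (EX_/SK_/DM_) or by topology (a single metabolite moved across the model
    boundary).  ``strip_copy_suffix`` collapses ``_copy1``-style duplicate
    ids found in some curated models (off by default — silent normalization
    can inflate TP).  ``by_stoichiometry`` matches reactions by canonical
    stoichiometric key instead of id string, for references whose reactions
    were renamed out of the shared namespace.
    """
    from .integration import canonical_key

    out: Set[str] = set()
    for rxn in _reactions_of(model):
        rid = rxn.id if hasattr(rxn, "id") else str(rxn)
        if rid.startswith(BOUNDARY_PREFIXES):
            continue
        stoich = getattr(rxn, "stoichiometry", None)
        if stoich is not None and len(stoich) == 1:
            continue  # one-sided single-metabolite boundary reaction
        if by_stoichiometry:
            if stoich is None:
                raise ValueError(
                    "by_stoichiometry requires reactions with stoichiometry"
                )
            out.add(repr(canonical_key(rxn)))
            continue
        if strip_copy_suffix:
            rid = _COPY_SUFFIX.sub("", rid)
        out.add(rid)
    return out


def confusion(draft_ids: Set[str], reference_ids: Set[str]) -> ConfusionCounts:
    """Set-arithmetic confusion counts over canonicalized reaction ids."""
    return ConfusionCounts(
        tp=len(draft_ids & reference_ids),
        fp=len(draft_ids - reference_ids),
        fn=len(reference_ids - draft_ids),
    )


def metrics(counts: ConfusionCounts) -> MetricTriple:
    """Precision, recall and F1 from confusion counts (exact formulas).

    Zero-denominator cases yield 0 for the affected metric and set the
    ``degenerate`` flag, so empty drafts still produce a report row.
    """
    degenerate = False
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, degenerate = 0.0, True
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return MetricTriple(precision=precision, recall=recall, f1=f1, degenerate=degenerate)


def format_report(rows: Mapping[str, Tuple[ConfusionCounts, MetricTriple]]) -> str:
    """TSV report, one row per draft: TP, FP, FN and 3-decimal P/R/F1."""
    lines = ["model\tTP\tFP\tFN\tprecision\trecall\tf1"]
    for label, (counts, triple) in rows.items():
        lines.append(
            f"{label}\t{counts.tp}\t{counts.fp}\t{counts.fn}"
            f"\t{triple.precision:.3f}\t{triple.recall:.3f}\t{triple.f1:.3f}"
        )
    return "\n".join(lines) + "\n"


def overlap_regions(
    id_sets: Sequence[Tuple[str, Set[str]]]
) -> Dict[Tuple[str, ...], int]:
    """Exact Venn-region counts for 2-7 labelled sets.

    Each element of the union contributes to exactly one region, identified
    by the sorted tuple of labels of the sets containing it; only non-empty
    regions appear in the result, and the region counts sum to the size of
    the union.
    """
    if not (2 <= len(id_sets) <= 7):
        raise ValueError("overlap_regions supports between 2 and 7 sets")
    labels = [label for label, _ in id_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")
    regions: Dict[Tuple[str, ...], int] = {}
    union: Set[str] = set().union(*(s for _, s in id_sets))
    for element in union:
        signature = tuple(sorted(label for label, s in id_sets if element in s))
        regions[signature] = regions.get(signature, 0) + 1
    return regions


def feature_sets(
    models: Sequence,
    feature: str = "reaction",
    cog_xref: Optional[Mapping[str, Set[str]]] = None,
) -> List[Tuple[str, Set[str]]]:
    """Per-model content sets for overlap/PCA analyses.

    ``feature`` selects reaction ids, metabolite full ids, or COG ids; the
    latter maps each model's GPR genes through ``cog_xref`` (gene id ->
    set of COG ids), the cross-reference of the query genome's functional
    annotation.
    """
    out: List[Tuple[str, Set[str]]] = []
    for model in models:
        label = getattr(model, "model_id", None) or getattr(model, "draft_id", "model")
        if feature == "reaction":
            ids = {r.id for r in _reactions_of(model)}
        elif feature == "metabolite":
            mets = getattr(model, "metabolites")
            ids = set(mets.keys() if isinstance(mets, dict) else {m.full_id for m in mets})
        elif feature == "cog":
            if cog_xref is None:
                raise ValueError("feature='cog' requires a gene -> COG cross-reference")
            from . import gpr as gpr_mod

            ids = set()
            for rxn in _reactions_of(model):
                rule = rxn.gpr_rule
                if rule is None:
                    continue
                for gene in gpr_mod.genes(rule):
                    ids |= set(cog_xref.get(gene, ()))
        else:
            raise ValueError(f"unknown feature {feature!r}")
        out.append((label, ids))
    return out


def model_content_pca(
    models: Sequence,
    feature: str = "reaction",
    cog_xref: Optional[Mapping[str, Set[str]]] = None,
) -> PcaResult:
    """PCA of model content: rows are models, columns content identifiers.

    The binary matrix goes through the same zero-variance drop, z-scoring
    and deterministic PCA as the organism COG profiles.
    """
    sets = feature_sets(models, feature=feature, cog_xref=cog_xref)
    if len(sets) < 3:
        raise ValueError("content PCA requires at least three models")
    columns = sorted(set().union(*(s for _, s in sets)))
    data = [[1 if c in s else 0 for c in columns] for _, s in sets]
    matrix = pd.DataFrame(data, index=[label for label, _ in sets], columns=columns)
    return pca_profiles(matrix)
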