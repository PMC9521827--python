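"""Draft-network assembly: GPR-driven reaction selection and deduplication.

Given template models and an ortholog map, a reaction is integrated into the
draft when its GPR can be assembled onto query genes under the active policy
(strict by default: at least one isozyme clause must be completely mapped;
reactions with missing GPRs are excluded).  Pooling several templates
introduces redundant reaction variants — the same transformation written in
the reverse direction, with or without explicit protons, or duplicated
across compartments — which are collapsed by a canonical stoichiometric key.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from . import gpr as gpr_mod
from .gpr import AssembledGpr, GeneRule
from .homology import OrthologMap, SearchEngine, SearchParams, build_ortholog_map
from .model_io import Gene, Metabolite, Reaction, ReactionUniverse, TemplateModel

__all__ = [
    "IntegrationPolicy",
    "SelectedReaction",
    "DraftNetwork",
    "DegenerateReactionError",
    "select_reactions",
    "canonical_key",
    "deduplicate",
    "build_draft",
    "BOUNDARY_PREFIXES",
]

logger = logging.getLogger(__name__)

#: Id prefixes of boundary pseudo-reactions (exchange, sink, demand).
BOUNDARY_PREFIXES = ("EX_", "SK_", "DM_")


class DegenerateReactionError(ValueError):
    """A reaction's canonical key is empty (e.g. protons only)."""


@dataclass(frozen=True)
class IntegrationPolicy:
    """Reaction-integration policy.

    strict
        Require a completely mapped isozyme clause (reactions with incomplete
        GPRs are excluded).  Non-strict admits partially mapped clauses,
        flagged as partial.
    include_missing_gpr
        Re-admit reactions without any GPR (spontaneous/boundary); off by
        default, matching a strict reconstruction.
    proton_ids
        Metabolite base ids stripped before duplicate detection (BiGG proton
        convention).
    collapse_compartments
        When True, reactions identical up to a consistent relabelling of
        compartments are merged; by default compartments are part of the key.
    """

    strict: bool = True
    include_missing_gpr: bool = False
    proton_ids: FrozenSet[str] = frozenset({"h"})
    collapse_compartments: bool = False


@dataclass
class SelectedReaction:
    """A template reaction admitted to the draft with its rewritten GPR."""

    reaction: Reaction
    gpr: Optional[GeneRule]
    flag: str  # "complete" | "partial" | "no_gpr"
    provenance: List[Tuple[str, str]] = field(default_factory=list)  # (model, rxn id)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [(self.reaction.source_model, self.reaction.id)]


def select_reactions(
    universe: ReactionUniverse,
    ortholog: Mapping[str, Iterable[str]],
    policy: IntegrationPolicy = IntegrationPolicy(),
) -> List[SelectedReaction]:
    """Evaluate every pooled reaction's GPR against the ortholog multimap.

    A reaction is selected iff :func:`biggdraft.gpr.assemble_partial_gpr`
    returns a rule under the policy; the assembled query-gene GPR is attached
    and the flag records whether a complete clause survived.
    """
    if isinstance(ortholog, OrthologMap):
        ortholog = ortholog.as_multimap()
    selected: List[SelectedReaction] = []
    for rxn in sorted(universe.reactions, key=lambda r: (r.id, r.source_model)):
        rule = rxn.gpr_rule
        if rule is None:
            if policy.include_missing_gpr:
                selected.append(SelectedReaction(reaction=rxn, gpr=None, flag="no_gpr"))
            continue
        assembled = gpr_mod.assemble_partial_gpr(
            rule, ortholog, strict=policy.strict, context=rxn.id
        )
        if assembled is None:
            continue
        selected.append(
            SelectedReaction(
                reaction=rxn,
                gpr=assembled.rule,
                flag="complete" if assembled.complete else "partial",
            )
        )
    return selected


# ---------------------------------------------------------------------------
# Canonical keys and deduplication
# ---------------------------------------------------------------------------

_Side = Tuple[Tuple[str, str, Fraction], ...]


def _sides(
    reaction: Reaction, proton_ids: FrozenSet[str]
) -> Tuple[List[Tuple[str, str, Fraction]], List[Tuple[str, str, Fraction]]]:
    left: List[Tuple[str, str, Fraction]] = []
    right: List[Tuple[str, str, Fraction]] = []
    for met, coeff in reaction.stoichiometry.items():
        if met.base_id in proton_ids:
            continue
        entry = (met.base_id, met.compartment, abs(coeff))
        (left if coeff < 0 else right).append(entry)
    return sorted(left), sorted(right)


def _relabel(sides: Tuple[_Side, _Side]) -> Tuple[_Side, _Side]:
    """Rename compartments to c0, c1, ... in order of first appearance."""
    mapping: Dict[str, str] = {}
    out: List[_Side] = []
    for side in sides:
        renamed = []
        for base, comp, coeff in side:
            if comp not in mapping:
                mapping[comp] = f"c{len(mapping)}"
            renamed.append((base, mapping[comp], coeff))
        out.append(tuple(sorted(renamed)))
    return out[0], out[1]


def canonical_key(
    reaction: Reaction,
    proton_ids: FrozenSet[str] = frozenset({"h"}),
    collapse_compartments: bool = False,
) -> Tuple[_Side, _Side]:
    """Direction-normalized, proton-stripped stoichiometric key.

    Two reactions receive equal keys iff they are duplicates under the three
    redundancy causes handled here: opposite written direction, explicit
    proton bookkeeping, and (only with ``collapse_compartments``) a
    consistent relabelling of compartments.  Coefficients compare as exact
    rationals; the lexicographically smaller side is placed first.
    """
    left, right = _sides(reaction, proton_ids)
    if not left and not right:
        raise DegenerateReactionError(
            f"reaction {reaction.id!r} has no non-proton metabolites"
        )
    forward: Tuple[_Side, _Side] = (tuple(left), tuple(right))
    backward: Tuple[_Side, _Side] = (tuple(right), tuple(left))
    if collapse_compartments:
        forward = _relabel(forward)
        backward = _relabel(backward)
    return min(forward, backward)


def _oriented_sides(reaction: Reaction, proton_ids: FrozenSet[str]) -> Tuple[_Side, _Side]:
    left, right = _sides(reaction, proton_ids)
    return tuple(left), tuple(right)


def deduplicate(
    selected: Sequence[SelectedReaction],
    policy: IntegrationPolicy = IntegrationPolicy(),
) -> List[SelectedReaction]:
    """Collapse redundant reaction variants to one representative per key.

    The representative is the member with the smallest (reaction id, source
    model id); merged GPRs are OR-joined and minimised by absorption; the
    representative becomes reversible when any variant was reversible or when
    two irreversible variants ran in opposite directions.  Provenance lists
    every merged source.  Idempotent by construction.
    """
    groups: Dict[Tuple, List[SelectedReaction]] = {}
    order: List[Tuple] = []
    for entry in selected:
        key = canonical_key(
            entry.reaction,
            proton_ids=policy.proton_ids,
            collapse_compartments=policy.collapse_compartments,
        )
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(entry)

    out: List[SelectedReaction] = []
    for key in order:
        members = sorted(
            groups[key],
            key=lambda e: (e.reaction.id, e.reaction.source_model),
        )
        rep = members[0]
        if len(members) == 1:
            out.append(rep)
            continue
        clauses: List = []
        any_no_gpr = False
        for m in members:
            if m.gpr is None:
                any_no_gpr = True
            else:
                clauses.extend(gpr_mod.decompose_or(m.gpr, context=rep.reaction.id))
        merged_rule = gpr_mod.clauses_to_rule(clauses) if clauses else None
        orientations = {
            min(
                (o := _oriented_sides(m.reaction, policy.proton_ids)),
                (o[1], o[0]),
            ) == o
            for m in members
        }
        reversible = any(m.reaction.reversible for m in members) or len(orientations) > 1
        rep_rxn = rep.reaction
        lb = rep_rxn.lower_bound
        ub = rep_rxn.upper_bound
        if reversible and not rep_rxn.reversible:
            lb, ub = -abs(ub if ub > 0 else 1000.0), abs(ub if ub > 0 else 1000.0)
        merged = Reaction(
            id=rep_rxn.id,
            stoichiometry=dict(rep_rxn.stoichiometry),
            name=rep_rxn.name,
            lower_bound=lb,
            upper_bound=ub,
            gpr_string=gpr_mod.render(merged_rule) if merged_rule else None,
            subsystem=rep_rxn.subsystem,
            source_model=rep_rxn.source_model,
        )
        flag = (
            "complete"
            if any(m.flag == "complete" for m in members)
            else ("no_gpr" if any_no_gpr and merged_rule is None else "partial")
        )
        out.append(
            SelectedReaction(
                reaction=merged,
                gpr=merged_rule,
                flag=flag,
                provenance=sorted(
                    {p for m in members for p in m.provenance}
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Draft network
# ---------------------------------------------------------------------------

@dataclass
class DraftNetwork:
    """The assembled draft: reactions with query-gene GPRs and provenance."""

    model_id: str
    organism: str = ""
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    flags: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)
    log: Dict = field(default_factory=dict)

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met.full_id not in self.metabolites:
                    raise ValueError(
                        f"draft reaction {rxn.id!r} references missing metabolite"
                    )
            rule = rxn.gpr_rule
            if rule is not None:
                missing = gpr_mod.genes(rule) - self.genes.keys()
                if missing:
                    raise ValueError(
                        f"draft reaction {rxn.id!r} GPR references non-query "
                        f"genes {sorted(missing)!r}"
                    )

    @classmethod
    def from_selected(
        cls,
        model_id: str,
        selected: Sequence[SelectedReaction],
        query_proteome: Mapping[str, Gene],
        organism: str = "",
        log: Optional[Dict] = None,
    ) -> "DraftNetwork":
        draft = cls(model_id=model_id, organism=organism, log=log or {})
        used_genes: Set[str] = set()
        for entry in selected:
            rxn = entry.reaction
            new_rxn = Reaction(
                id=rxn.id,
                stoichiometry=dict(rxn.stoichiometry),
                name=rxn.name,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                gpr_string=gpr_mod.render(entry.gpr) if entry.gpr else None,
                subsystem=rxn.subsystem,
                source_model=rxn.source_model,
            )
            draft.reactions[new_rxn.id] = new_rxn
            draft.flags[new_rxn.id] = entry.flag
            draft.provenance[new_rxn.id] = list(entry.provenance)
            for met in rxn.stoichiometry:
                draft.metabolites[met.full_id] = met
            if entry.gpr is not None:
                used_genes |= gpr_mod.genes(entry.gpr)
        for gid in sorted(used_genes):
            gene = query_proteome.get(gid)
            draft.genes[gid] = gene if gene is not None else Gene(id=gid)
        draft.validate()
        return draft


def _pick_templates(
    templates: Sequence[TemplateModel],
    mode: str,
    k: int,
    seed: Optional[int],
    annotations,
    target_organism: Optional[str],
) -> List[TemplateModel]:
    if mode == "all":
        return list(templates)
    if mode == "random":
        if k > len(templates):
            raise ValueError(f"k={k} exceeds the {len(templates)} available templates")
        rng = random.Random(seed)
        ordered = sorted(templates, key=lambda t: t.model_id)
        return rng.sample(ordered, k)
    if mode == "selected":
        if annotations is None or target_organism is None:
            raise ValueError(
                "mode='selected' requires COG annotations and a target organism"
            )
        from . import template_selection as ts

        matrix = ts.build_profile_matrix(annotations)
        distances = ts.metabolic_distance(matrix)
        closest = ts.top_k_closest(distances, target_organism, k=k)
        by_organism = {t.organism: t for t in templates}
        picked = []
        for org in closest:
            if org in by_organism:
                picked.append(by_organism[org])
        if not picked:
            raise ValueError(
                f"no template models match the selected organisms {closest!r}"
            )
        return picked
    raise ValueError(f"unknown template mode {mode!r}")


def build_draft(
    templates: Sequence[TemplateModel],
    query_proteome: Mapping[str, Gene],
    params: SearchParams = SearchParams(),
    engine: Optional[SearchEngine] = None,
    mode: str = "all",
    k: int = 3,
    seed: Optional[int] = None,
    policy: IntegrationPolicy = IntegrationPolicy(),
    annotations=None,
    target_organism: Optional[str] = None,
    draft_id: str = "draft",
) -> DraftNetwork:
    """End-to-end reconstruction: template choice -> per-template
    bidirectional search and ortholog map -> GPR-driven selection ->
    deduplication -> :class:`DraftNetwork`.

    The ortholog map is computed per template model (gene ids are only
    unique within a template), then selected reactions are pooled and
    deduplicated across templates.  The run log records template ids,
    per-stage counts, parameters and the seed.
    """
    if not templates:
        raise ValueError("no template models supplied")
    if engine is None:
        from .homology import BlastEngine

        engine = BlastEngine()
    chosen = _pick_templates(templates, mode, k, seed, annotations, target_organism)

    selected_pool: List[SelectedReaction] = []
    per_template: Dict[str, Dict[str, int]] = {}
    for template in chosen:
        omap = build_ortholog_map(
            query_proteome, template.protein_sequences(), params, engine
        )
        universe = ReactionUniverse.from_models([template])
        picks = select_reactions(universe, omap, policy)
        selected_pool.extend(picks)
        per_template[template.model_id] = {
            "ortholog_pairs": len(omap),
            "selected_reactions": len(picks),
        }
        logger.info(
            "template %s: %d ortholog pairs, %d reactions selected",
            template.model_id,
            len(omap),
            len(picks),
        )

    merged = deduplicate(selected_pool, policy)
    log = {
        "mode": mode,
        "k": k,
        "seed": seed,
        "templates": [t.model_id for t in chosen],
        "params": {
            "max_evalue": params.max_evalue,
            "min_bitscore": params.min_bitscore,
            "min_query_coverage": params.min_query_coverage,
            "scoring_matrix": params.scoring_matrix,
        },
        "policy": {
            "strict": policy.strict,
            "include_missing_gpr": policy.include_missing_gpr,
            "proton_ids": sorted(policy.proton_ids),
            "collapse_compartments": policy.collapse_compartments,
        },
        "per_template": per_template,
        "selected_total": len(selected_pool),
        "after_deduplication": len(merged),
    }
    return DraftNetwork.from_selected(
        draft_id, merged, query_proteome, organism=target_organism or "", log=log
    )
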