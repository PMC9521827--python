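"""Deterministic synthetic template collections with known ground truth.

The generator emulates, at desk scale, the inputs of template-based draft
reconstruction: a collection of template models (BiGG-style JSON with
protein sequences), a query proteome planted with orthologs of template
proteins, per-organism COG annotation tables, and a curated "reference"
model assembled so the draft's precision/recall/F1 against it are known in
closed form.  Everything is derived from a single integer seed; the same
:class:`FixtureSpec` always produces byte-identical output directories.

Planted structure recorded in :class:`GroundTruth` — and computed during
construction, not by running the pipeline:

* ortholog pairs (template gene, query gene), with the subset whose copied
  sequence is unmutated (recoverable by an exact-match search);
* per-reaction isozyme clause lists, covering the single-gene, OR-only,
  AND-only and mixed rule shapes;
* duplicate reaction groups (reverse-written and protonation variants) that
  deduplication must collapse;
* the expected draft reaction set under the strict policy with exact
  homology, and the reference set derived from it by removing a known
  fraction (the draft's future FPs) and adding known absent reactions (FNs).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .model_io import (
    Gene,
    Metabolite,
    Reaction,
    TemplateModel,
    write_draft_sbml,
    write_template_json,
)
from .template_selection import METABOLISM_CATEGORIES, CogAnnotation

__all__ = ["FixtureSpec", "GroundTruth", "FixtureBundle", "generate", "mutate_sequences"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GPR_SHAPES = ("single", "or_only", "and_only", "mixed")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; same spec + seed => identical bytes."""

    seed: int = 1
    n_templates: int = 3
    reactions_per_template: int = 25
    genes_per_template: int = 18
    metabolite_pool: int = 30
    gpr_shape_weights: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    duplicate_groups: int = 3
    ortholog_identity: float = 0.8
    mutation_rate: float = 0.0
    protein_length: int = 80
    proton_id: str = "h"
    decoy_queries: int = 5
    fn_reactions: int = 5
    fp_fraction: float = 0.2
    n_cogs: int = 40

    def validate(self) -> None:
        if self.n_templates < 1 or self.reactions_per_template < 4:
            raise ValueError("need >=1 template with >=4 reactions each")
        if self.genes_per_template < 6:
            raise ValueError("need >=6 genes per template")
        if self.duplicate_groups > self.reactions_per_template:
            raise ValueError(
                "duplicate_groups cannot exceed reactions_per_template"
            )
        if not (0.0 <= self.ortholog_identity <= 1.0):
            raise ValueError("ortholog_identity must be in [0, 1]")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        if not (0.0 <= self.fp_fraction < 1.0):
            raise ValueError("fp_fraction must be in [0, 1)")
        if self.protein_length < 60:
            raise ValueError("protein_length must be >= 60")


@dataclass
class GroundTruth:
    """Everything the generator planted, serializable to JSON."""

    ortholog_pairs: List[Tuple[str, str]] = field(default_factory=list)
    exact_ortholog_pairs: List[Tuple[str, str]] = field(default_factory=list)
    reaction_clauses: Dict[str, List[List[str]]] = field(default_factory=dict)
    expected_selected: Dict[str, List[str]] = field(default_factory=dict)
    duplicate_groups: List[Dict] = field(default_factory=list)
    expected_draft_reaction_ids: List[str] = field(default_factory=list)
    reference_reaction_ids: List[str] = field(default_factory=list)
    expected_confusion: Dict[str, int] = field(default_factory=dict)
    expected_metrics: Dict[str, float] = field(default_factory=dict)
    profile_matrix: Dict[str, List[str]] = field(default_factory=dict)
    query_residue_total: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"


@dataclass
class FixtureBundle:
    """In-memory fixture: models, proteome, annotations, reference, truth."""

    spec: FixtureSpec
    templates: List[TemplateModel]
    query_proteome: Dict[str, Gene]
    annotations: List[CogAnnotation]
    reference: TemplateModel
    truth: GroundTruth


def _random_sequence(rng: random.Random, length: int, taken: Set[str]) -> str:
    while True:
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
        if seq not in taken:
            taken.add(seq)
            return seq


def _mutate_one(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice(AMINO_ACIDS)
    return "".join(out)


def mutate_sequences(
    sequences: Mapping[str, str], rate: float, seed: int
) -> Dict[str, str]:
    """Per-residue substitution at the given rate (length-preserving,
    deterministic under seed; a drawn substitute may equal the original)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = random.Random(seed)
    return {sid: _mutate_one(seq, rate, rng) for sid, seq in sequences.items()}


def _clause_string(clauses: Sequence[FrozenSet[str]]) -> str:
    parts = []
    for clause in clauses:
        ordered = sorted(clause)
        parts.append(ordered[0] if len(ordered) == 1 else "(" + " and ".join(ordered) + ")")
    return " or ".join(parts)


def _plain_key(
    stoich: Mapping[str, Fraction], proton_id: str
) -> Tuple[Tuple, Tuple]:
    """Generator-side duplicate key: proton-stripped, direction-normalized.

    Computed from raw id/coefficient pairs during construction so the planted
    distinct-group count never depends on pipeline code.
    """
    left, right = [], []
    for full_id, coeff in stoich.items():
        base = full_id.rsplit("_", 1)[0]
        if base == proton_id:
            continue
        (left if coeff < 0 else right).append((full_id, abs(coeff)))
    sides = (tuple(sorted(left)), tuple(sorted(right)))
    return min(sides, (sides[1], sides[0]))


def generate(
    spec: FixtureSpec, out_dir: Optional[Union[str, Path]] = None
) -> FixtureBundle:
    """Generate a fixture bundle, optionally writing it to ``out_dir``.

    Layout on disk: ``templates/<id>.json`` and ``templates/<id>.faa``,
    ``query.faa``, ``annotations/<organism>.tsv``, ``reference.xml`` and
    ``ground_truth.json``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    taken_seqs: Set[str] = set()
    truth = GroundTruth()

    # shared metabolite pool in compartment "c", plus the proton
    pool = [
        Metabolite(base_id=f"m{j:03d}", compartment="c")
        for j in range(spec.metabolite_pool)
    ]
    proton = Metabolite(base_id=spec.proton_id, compartment="c")
    used_keys: Set[Tuple] = set()

    templates: List[TemplateModel] = []
    reactions_by_id: Dict[str, Tuple[str, Reaction]] = {}

    def _fresh_stoich() -> Dict[Metabolite, Fraction]:
        while True:
            n_sub = rng.randint(1, 2)
            n_prod = rng.randint(1, 2)
            mets = rng.sample(pool, n_sub + n_prod)
            stoich = {}
            for m in mets[:n_sub]:
                stoich[m] = Fraction(-(2 if rng.random() < 0.2 else 1))
            for m in mets[n_sub:]:
                stoich[m] = Fraction(2 if rng.random() < 0.2 else 1)
            key = _plain_key({m.full_id: c for m, c in stoich.items()}, spec.proton_id)
            if key not in used_keys:
                used_keys.add(key)
                return stoich

    for t in range(spec.n_templates):
        model = TemplateModel(model_id=f"tmpl{t}", organism=f"org{t}")
        model.metabolites = {m.full_id: m for m in pool}
        model.metabolites[proton.full_id] = proton
        gene_ids = [f"{model.model_id}_g{i:03d}" for i in range(spec.genes_per_template)]
        for gid in gene_ids:
            model.genes[gid] = Gene(
                id=gid,
                protein_sequence=_random_sequence(rng, spec.protein_length, taken_seqs),
                model_of_origin=model.model_id,
            )
        for i in range(spec.reactions_per_template):
            # guarantee coverage of all four rule shapes in every template
            shape = (
                GPR_SHAPES[i]
                if i < 4
                else rng.choices(GPR_SHAPES, weights=spec.gpr_shape_weights)[0]
            )
            if shape == "single":
                clauses = [frozenset(rng.sample(gene_ids, 1))]
            elif shape == "or_only":
                clauses = [frozenset({g}) for g in rng.sample(gene_ids, rng.randint(2, 3))]
            elif shape == "and_only":
                clauses = [frozenset(rng.sample(gene_ids, rng.randint(2, 3)))]
            else:  # mixed: at least one multi-gene clause plus another clause
                first = frozenset(rng.sample(gene_ids, 2))
                rest = frozenset(rng.sample(gene_ids, rng.randint(1, 2)))
                clauses = [first, rest] if rest != first else [first, frozenset(rng.sample(gene_ids, 1))]
            rid = f"R{t}_{i:03d}"
            rxn = Reaction(
                id=rid,
                stoichiometry=_fresh_stoich(),
                lower_bound=0.0 if rng.random() < 0.5 else -1000.0,
                upper_bound=1000.0,
                gpr_string=_clause_string(clauses),
                source_model=model.model_id,
            )
            model.reactions[rid] = rxn
            reactions_by_id[rid] = (model.model_id, rxn)
            truth.reaction_clauses[rid] = sorted(sorted(c) for c in clauses)
        templates.append(model)

    # plant query orthologs: a fraction of template proteins copied (with
    # optional point mutations) under q_<gene> ids, plus unrelated decoys
    query: Dict[str, Gene] = {}
    exact_genes: Set[str] = set()
    mut_rng = random.Random(spec.seed + 101)
    for model in templates:
        for gid, gene in model.genes.items():
            if rng.random() < spec.ortholog_identity:
                qid = f"q_{gid}"
                seq = _mutate_one(gene.protein_sequence, spec.mutation_rate, mut_rng)
                query[qid] = Gene(id=qid, protein_sequence=seq, model_of_origin="query")
                truth.ortholog_pairs.append((gid, qid))
                if seq == gene.protein_sequence:
                    exact_genes.add(gid)
                    truth.exact_ortholog_pairs.append((gid, qid))

    # duplicate groups: a satisfiable base reaction gets a redundant variant
    # (reverse-written or protonation), guarded by its own guaranteed ortholog
    def _satisfiable(rid: str) -> bool:
        return any(
            set(clause) <= exact_genes for clause in truth.reaction_clauses[rid]
        )

    candidates = sorted(rid for rid in reactions_by_id if _satisfiable(rid))
    if len(candidates) < spec.duplicate_groups:
        raise ValueError(
            "not enough satisfiable reactions to plant the requested duplicate "
            "groups; raise ortholog_identity or reaction counts"
        )
    bases = rng.sample(candidates, spec.duplicate_groups)
    for g, base_id in enumerate(sorted(bases)):
        model_id, base = reactions_by_id[base_id]
        model = next(m for m in templates if m.model_id == model_id)
        variant_type = rng.choice(("reversed", "protonation"))
        dup_gid = f"{model_id}_dup{g:02d}"
        model.genes[dup_gid] = Gene(
            id=dup_gid,
            protein_sequence=_random_sequence(rng, spec.protein_length, taken_seqs),
            model_of_origin=model_id,
        )
        qid = f"q_{dup_gid}"
        query[qid] = Gene(
            id=qid,
            protein_sequence=model.genes[dup_gid].protein_sequence,
            model_of_origin="query",
        )
        truth.ortholog_pairs.append((dup_gid, qid))
        truth.exact_ortholog_pairs.append((dup_gid, qid))
        exact_genes.add(dup_gid)
        if variant_type == "reversed":
            var_id = f"{base_id}Xr"
            stoich = {m: -c for m, c in base.stoichiometry.items()}
        else:
            var_id = f"{base_id}Xh"
            stoich = dict(base.stoichiometry)
            stoich[proton] = stoich.get(proton, Fraction(0)) + Fraction(1)
        variant = Reaction(
            id=var_id,
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr_string=dup_gid,
            source_model=model_id,
        )
        model.reactions[var_id] = variant
        reactions_by_id[var_id] = (model_id, variant)
        truth.reaction_clauses[var_id] = [[dup_gid]]
        truth.duplicate_groups.append(
            {
                "type": variant_type,
                "members": sorted([base_id, var_id]),
                "representative": min(base_id, var_id),
            }
        )

    decoy_rng = random.Random(spec.seed + 202)
    for d in range(spec.decoy_queries):
        qid = f"q_decoy{d:02d}"
        query[qid] = Gene(
            id=qid,
            protein_sequence=_random_sequence(decoy_rng, spec.protein_length, taken_seqs),
            model_of_origin="query",
        )

    # expected strict-policy draft under exact homology, before any pipeline
    # code runs: a reaction is selected iff some clause is fully covered by
    # exactly-copied orthologs; each duplicate group then collapses onto its
    # representative id
    for model in templates:
        truth.expected_selected[model.model_id] = sorted(
            rid for rid in model.reactions if _satisfiable(rid)
        )
    selected_all = {
        rid for rids in truth.expected_selected.values() for rid in rids
    }
    variant_ids = {
        m for grp in truth.duplicate_groups for m in grp["members"]
    } - {grp["representative"] for grp in truth.duplicate_groups}
    truth.expected_draft_reaction_ids = sorted(selected_all - variant_ids)

    # reference model: expected draft minus a known FP share, plus known FNs
    ref_rng = random.Random(spec.seed + 303)
    draft_ids = list(truth.expected_draft_reaction_ids)
    n_keep = round((1.0 - spec.fp_fraction) * len(draft_ids))
    kept = sorted(ref_rng.sample(draft_ids, n_keep)) if draft_ids else []
    reference = TemplateModel(model_id="reference", organism="query_org")
    reference.metabolites = {m.full_id: m for m in pool}
    reference.metabolites[proton.full_id] = proton
    for rid in kept:
        _, rxn = reactions_by_id[rid]
        reference.reactions[rid] = Reaction(
            id=rid,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr_string=rxn.gpr_string,
            source_model="reference",
        )
        for clause in truth.reaction_clauses[rid]:
            for gid in clause:
                if gid not in reference.genes:
                    reference.genes[gid] = Gene(id=gid, model_of_origin="reference")
    fn_ids = []
    for i in range(spec.fn_reactions):
        rid = f"RFN{i:03d}"
        gid = f"refg{i:03d}"
        reference.genes[gid] = Gene(id=gid, model_of_origin="reference")
        reference.reactions[rid] = Reaction(
            id=rid,
            stoichiometry=_fresh_stoich(),
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr_string=gid,
            source_model="reference",
        )
        fn_ids.append(rid)
    # boundary pseudo-reactions that scoring must ignore
    ex_met = pool[0]
    reference.reactions["EX_" + ex_met.full_id] = Reaction(
        id="EX_" + ex_met.full_id,
        stoichiometry={ex_met: Fraction(-1)},
        lower_bound=-1000.0,
        upper_bound=1000.0,
        source_model="reference",
    )
    reference.reactions["unlabeled_sink"] = Reaction(
        id="unlabeled_sink",
        stoichiometry={pool[1]: Fraction(-1)},
        lower_bound=0.0,
        upper_bound=1000.0,
        source_model="reference",
    )
    truth.reference_reaction_ids = sorted(kept + fn_ids)
    tp, fp, fn = len(kept), len(draft_ids) - len(kept), len(fn_ids)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    truth.expected_confusion = {"tp": tp, "fp": fp, "fn": fn}
    truth.expected_metrics = {"precision": precision, "recall": recall, "f1": f1}

    # COG annotation tables: template organisms plus the query organism
    cog_pool = [f"COG{j + 1:04d}" for j in range(spec.n_cogs)]
    cog_rng = random.Random(spec.seed + 404)
    organisms = [m.organism for m in templates] + ["query_org"]
    annotations: List[CogAnnotation] = []
    metabolism_letters = sorted(METABOLISM_CATEGORIES)
    for org in organisms:
        present = sorted(c for c in cog_pool if cog_rng.random() < 0.5)
        rows: List[Tuple[str, str, str]] = []
        for j, cog in enumerate(present):
            rows.append((f"{org}_p{j:03d}", cog, cog_rng.choice(metabolism_letters)))
        # non-metabolic rows that profile building must filter out
        rows.append((f"{org}_pX0", "COG9001", "J"))
        rows.append((f"{org}_pX1", "COG9002", "L"))
        annotations.append(CogAnnotation(organism=org, rows=rows))
        truth.profile_matrix[org] = present

    truth.ortholog_pairs.sort()
    truth.exact_ortholog_pairs.sort()
    truth.query_residue_total = sum(
        len(g.protein_sequence) for g in query.values()
    )

    bundle = FixtureBundle(
        spec=spec,
        templates=templates,
        query_proteome=query,
        annotations=annotations,
        reference=reference,
        truth=truth,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_fasta(genes: Mapping[str, Gene], path: Path) -> None:
    with open(path, "w") as fh:
        for gid in genes:
            fh.write(f">{gid}\n{genes[gid].protein_sequence}\n")


def _write_bundle(bundle: FixtureBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tdir = out_dir / "templates"
    tdir.mkdir(exist_ok=True)
    for model in bundle.templates:
        write_template_json(model, tdir / f"{model.model_id}.json")
        _write_fasta(model.genes, tdir / f"{model.model_id}.faa")
    _write_fasta(bundle.query_proteome, out_dir / "query.faa")
    adir = out_dir / "annotations"
    adir.mkdir(exist_ok=True)
    for ann in bundle.annotations:
        with open(adir / f"{ann.organism}.tsv", "w") as fh:
            fh.write("protein_id\tcog_id\tcategory\tevalue\n")
            for protein, cog, category in ann.rows:
                fh.write(f"{protein}\t{cog}\t{category}\t1e-30\n")
    write_draft_sbml(bundle.reference, out_dir / "reference.xml")
    with open(out_dir / "ground_truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())
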