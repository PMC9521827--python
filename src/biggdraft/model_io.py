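"""Reading and writing template/draft metabolic models and flat inputs.

Supported formats:

* BiGG/COBRA JSON model schema (top-level ``metabolites``, ``reactions``,
  ``genes``; reactions carry ``gene_reaction_rule`` strings);
* SBML Level 3 Version 1 with the FBC v2 package (gene products and
  ``geneProductAssociation`` trees), via python-libsbml;
* amino-acid FASTA proteomes, via Biopython;
* BLAST-outfmt-6-like tabular hit files, extended with a query-length column.

Stoichiometric coefficients are held as exact :class:`fractions.Fraction`
values so that reaction deduplication can compare them exactly; they are
serialized as decimals in SBML.  GPR strings are stored verbatim on load and
parsed on demand by :mod:`biggdraft.gpr`, so an unparseable rule fails at
evaluation time with its reaction id, not at load time.  All file paths are
accepted plain or gzip-compressed (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import json
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, IO, Iterable, List, Mapping, Optional, Union

import libsbml
from Bio import SeqIO

from . import gpr as gpr_mod
from .gpr import And, GeneRef, GeneRule, Or
from .homology import HomologyHit

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "TemplateModel",
    "ReactionUniverse",
    "ModelFormatError",
    "ModelIntegrityError",
    "read_template_json",
    "write_template_json",
    "read_template_sbml",
    "write_draft_sbml",
    "read_proteome_fasta",
    "read_hits_table",
    "split_compartment",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
_DEFAULT_LB, _DEFAULT_UB = -1000.0, 1000.0


class ModelFormatError(ValueError):
    """Malformed input file (bad JSON/SBML/FASTA/TSV structure)."""


class ModelIntegrityError(ValueError):
    """A loaded model violates referential integrity."""


def _open_text(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def split_compartment(species_id: str) -> tuple:
    """Split a BiGG-style metabolite id into (base_id, compartment).

    The split is on the LAST underscore, so double-underscore base ids such
    as ``glc__D`` in ``glc__D_c`` survive intact.
    """
    base, sep, comp = species_id.rpartition("_")
    if not sep or not base or not comp:
        raise ModelFormatError(
            f"metabolite id {species_id!r} has no compartment suffix"
        )
    return base, comp


@dataclass(frozen=True)
class Metabolite:
    base_id: str
    compartment: str
    name: str = ""
    formula: str = ""
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.base_id:
            raise ValueError("metabolite base_id must be non-empty")
        if not self.compartment:
            raise ValueError("metabolite compartment must be non-empty")

    @property
    def full_id(self) -> str:
        return f"{self.base_id}_{self.compartment}"


@dataclass(frozen=True)
class Gene:
    id: str
    protein_sequence: Optional[str] = None
    model_of_origin: str = ""

    def __post_init__(self) -> None:
        if self.protein_sequence is not None:
            bad = set(self.protein_sequence.upper()) - _VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"gene {self.id!r}: invalid residues {sorted(bad)!r}"
                )


@dataclass
class Reaction:
    """A metabolic reaction: reactants carry negative coefficients, products
    positive; the GPR string is parsed lazily via :attr:`gpr_rule`."""

    id: str
    stoichiometry: Dict[Metabolite, Fraction]
    name: str = ""
    lower_bound: float = _DEFAULT_LB
    upper_bound: float = _DEFAULT_UB
    gpr_string: Optional[str] = None
    subsystem: str = ""
    source_model: str = ""
    _gpr_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r} has no metabolites")
        for met, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ValueError(
                    f"reaction {self.id!r}: zero coefficient for {met.full_id}"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def gpr_rule(self) -> Optional[GeneRule]:
        """Parsed GPR tree (cached); raises GprParseError with context."""
        if self._gpr_cache is None:
            try:
                rule = gpr_mod.parse_gpr(self.gpr_string)
            except gpr_mod.GprParseError as exc:
                raise gpr_mod.GprParseError(
                    f"reaction {self.id!r}: {exc}", exc.position
                ) from exc
            object.__setattr__(self, "_gpr_cache", (rule,))
        return self._gpr_cache[0]

    def reactants(self) -> Dict[Metabolite, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> Dict[Metabolite, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class TemplateModel:
    """One source model: genes with protein sequences, metabolites, reactions."""

    model_id: str
    organism: str = ""
    genes: Dict[str, Gene] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)

    def protein_sequences(self) -> Dict[str, str]:
        return {
            gid: g.protein_sequence
            for gid, g in self.genes.items()
            if g.protein_sequence
        }

    def validate(self) -> None:
        """Assert referential integrity (metabolite and gene references)."""
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met.full_id not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id!r} references undeclared metabolite "
                        f"{met.full_id!r}"
                    )
            if rxn.gpr_string:
                try:
                    rule = rxn.gpr_rule
                except gpr_mod.GprParseError:
                    continue  # unparseable rules are deferred to evaluation
                missing = gpr_mod.genes(rule) - self.genes.keys()
                if missing:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id!r} GPR references undeclared genes "
                        f"{sorted(missing)!r}"
                    )


@dataclass
class ReactionUniverse:
    """Reactions pooled from one or more template models; ids may repeat
    across sources before deduplication, provenance lives in
    ``Reaction.source_model``."""

    reactions: List[Reaction] = field(default_factory=list)

    @classmethod
    def from_models(cls, models: Iterable[TemplateModel]) -> "ReactionUniverse":
        pool: List[Reaction] = []
        for model in models:
            for rxn in model.reactions.values():
                if not rxn.source_model:
                    rxn = Reaction(
                        id=rxn.id,
                        stoichiometry=dict(rxn.stoichiometry),
                        name=rxn.name,
                        lower_bound=rxn.lower_bound,
                        upper_bound=rxn.upper_bound,
                        gpr_string=rxn.gpr_string,
                        subsystem=rxn.subsystem,
                        source_model=model.model_id,
                    )
                pool.append(rxn)
        return cls(reactions=pool)

    def __len__(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------
# BiGG/COBRA JSON
# ---------------------------------------------------------------------------

def _coeff_to_fraction(value) -> Fraction:
    # exact for ints and decimal-printed floats alike
    return Fraction(str(value))


def read_template_json(path: Union[str, Path]) -> TemplateModel:
    """Read a BiGG/COBRA JSON model file into a :class:`TemplateModel`.

    Protein sequences are taken from an optional ``protein_sequence`` key on
    gene entries when present (BiGG distributions ship sequences separately;
    attach them with :func:`read_proteome_fasta` otherwise).
    """
    with _open_text(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: malformed JSON: {exc}") from exc
    for key in ("metabolites", "reactions", "genes"):
        if key not in raw:
            raise ModelFormatError(f"{path}: missing required key {key!r}")
    model = TemplateModel(
        model_id=raw.get("id", Path(path).stem),
        organism=raw.get("organism", raw.get("name", "")),
    )
    for entry in raw["metabolites"]:
        full = entry["id"]
        comp = entry.get("compartment")
        if comp and full.endswith("_" + comp):
            base = full[: -(len(comp) + 1)]
        else:
            base, comp = split_compartment(full)
        met = Metabolite(
            base_id=base,
            compartment=comp,
            name=entry.get("name", "") or "",
            formula=entry.get("formula", "") or "",
            charge=entry.get("charge"),
        )
        model.metabolites[met.full_id] = met
    for entry in raw["genes"]:
        gene = Gene(
            id=entry["id"],
            protein_sequence=entry.get("protein_sequence"),
            model_of_origin=model.model_id,
        )
        model.genes[gene.id] = gene
    for entry in raw["reactions"]:
        stoich: Dict[Metabolite, Fraction] = {}
        for met_id, coeff in entry.get("metabolites", {}).items():
            if met_id not in model.metabolites:
                raise ModelIntegrityError(
                    f"{path}: reaction {entry.get('id')!r} references "
                    f"undeclared metabolite {met_id!r}"
                )
            stoich[model.metabolites[met_id]] = _coeff_to_fraction(coeff)
        rxn = Reaction(
            id=entry["id"],
            stoichiometry=stoich,
            name=entry.get("name", "") or "",
            lower_bound=float(entry.get("lower_bound", _DEFAULT_LB)),
            upper_bound=float(entry.get("upper_bound", _DEFAULT_UB)),
            gpr_string=entry.get("gene_reaction_rule") or None,
            subsystem=entry.get("subsystem", "") or "",
            source_model=model.model_id,
        )
        model.reactions[rxn.id] = rxn
    model.validate()
    return model


def write_template_json(model: TemplateModel, path: Union[str, Path]) -> None:
    """Write a model in the BiGG/COBRA JSON dialect (deterministic layout)."""
    raw = {
        "id": model.model_id,
        "organism": model.organism,
        "metabolites": [
            {
                "id": m.full_id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in sorted(model.metabolites.values(), key=lambda m: m.full_id)
        ],
        "genes": [
            {"id": g.id, "protein_sequence": g.protein_sequence}
            for g in sorted(model.genes.values(), key=lambda g: g.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {
                    m.full_id: (
                        int(c) if c.denominator == 1 else float(c)
                    )
                    for m, c in sorted(
                        r.stoichiometry.items(), key=lambda kv: kv[0].full_id
                    )
                },
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr_string or "",
                "subsystem": r.subsystem,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
    }
    with _open_text(path, "wt") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_SID_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    """Sanitize an identifier into a valid SBML SId; originals are preserved
    via species/gene-product metadata (labels), so round trips are lossless
    for the label."""
    out = _SID_SAFE.sub("_", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return prefix + out


def _association_to_rule(
    assoc: libsbml.FbcAssociation, sid_to_label: Mapping[str, str]
) -> GeneRule:
    if isinstance(assoc, libsbml.GeneProductRef):
        sid = assoc.getGeneProduct()
        return GeneRef(sid_to_label.get(sid, sid))
    children = [
        _association_to_rule(assoc.getAssociation(i), sid_to_label)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return gpr_mod.and_(children)
    if isinstance(assoc, libsbml.FbcOr):
        return gpr_mod.or_(children)
    raise ModelFormatError(f"unsupported FBC association node {assoc!r}")


def _rule_to_association(parent, rule: GeneRule, label_to_sid: Mapping[str, str]) -> None:
    if isinstance(rule, GeneRef):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(label_to_sid[rule.gene_id])
        return
    node = parent.createAnd() if isinstance(rule, And) else parent.createOr()
    for child in rule.children:
        _rule_to_association(node, child, label_to_sid)


def read_template_sbml(path: Union[str, Path]) -> TemplateModel:
    """Read an SBML Level 3 + FBC model into a :class:`TemplateModel`.

    FBC gene-product associations become GPR rules keyed by gene-product
    label (falling back to the SId).  Reactions without an association are
    loaded with an absent GPR and a warning.
    """
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = "; ".join(
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        )
        raise ModelFormatError(f"{path}: SBML parse errors: {msgs}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no model element")
    model = TemplateModel(
        model_id=sbml_model.getId() or Path(path).stem,
        organism=sbml_model.getName() or "",
    )
    mplug = sbml_model.getPlugin("fbc")
    sid_to_label: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            sid_to_label[gp.getId()] = label
            model.genes[label] = Gene(
                id=label, protein_sequence=None, model_of_origin=model.model_id
            )

    def _param_value(pid: str, default: float) -> float:
        param = sbml_model.getParameter(pid) if pid else None
        return param.getValue() if param is not None else default

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = sp.getId()
        raw_id = sid[2:] if sid.startswith("M_") else sid
        comp = sp.getCompartment()
        if comp and raw_id.endswith("_" + comp):
            base = raw_id[: -(len(comp) + 1)]
        else:
            base, comp = split_compartment(raw_id)
        splug = sp.getPlugin("fbc")
        charge = None
        formula = ""
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
        met = Metabolite(
            base_id=base,
            compartment=comp,
            name=sp.getName() or "",
            formula=formula,
            charge=charge,
        )
        model.metabolites[met.full_id] = met

    species_by_sid = {
        sbml_model.getSpecies(i).getId(): sbml_model.getSpecies(i)
        for i in range(sbml_model.getNumSpecies())
    }
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        rid = rid[2:] if rid.startswith("R_") else rid
        stoich: Dict[Metabolite, Fraction] = {}

        def _add(ref: libsbml.SpeciesReference, sign: int) -> None:
            sp = species_by_sid[ref.getSpecies()]
            raw_id = sp.getId()
            raw_id = raw_id[2:] if raw_id.startswith("M_") else raw_id
            met = model.metabolites[
                raw_id
                if raw_id in model.metabolites
                else Metabolite(*split_compartment(raw_id)).full_id
            ]
            coeff = sign * _coeff_to_fraction(ref.getStoichiometry())
            stoich[met] = stoich.get(met, Fraction(0)) + coeff
            if stoich[met] == 0:
                del stoich[met]

        for j in range(rx.getNumReactants()):
            _add(rx.getReactant(j), -1)
        for j in range(rx.getNumProducts()):
            _add(rx.getProduct(j), +1)

        rplug = rx.getPlugin("fbc")
        lb, ub = _DEFAULT_LB, _DEFAULT_UB
        gpr_string = None
        if rplug is not None:
            lb = _param_value(
                rplug.getLowerFluxBound(), _DEFAULT_LB if rx.getReversible() else 0.0
            )
            ub = _param_value(rplug.getUpperFluxBound(), _DEFAULT_UB)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gpr_string = gpr_mod.render(
                    _association_to_rule(gpa.getAssociation(), sid_to_label)
                )
        else:
            lb = _DEFAULT_LB if rx.getReversible() else 0.0
        if gpr_string is None:
            warnings.warn(
                f"{path}: reaction {rid!r} has no FBC gene association",
                stacklevel=2,
            )
        model.reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            name=rx.getName() or "",
            lower_bound=lb,
            upper_bound=ub,
            gpr_string=gpr_string,
            source_model=model.model_id,
        )
    model.validate()
    return model


def write_draft_sbml(draft, path: Union[str, Path]) -> None:
    """Write a draft network (or template model) as SBML L3V1 + FBC v2.

    ``draft`` needs ``model_id``-like identity plus iterables of reactions,
    metabolites and genes; both :class:`TemplateModel` and
    :class:`biggdraft.integration.DraftNetwork` satisfy the contract.
    Boundary reactions keep their EX_/SK_/DM_ id prefixes.
    """
    reactions = list(
        draft.reactions.values() if isinstance(draft.reactions, dict) else draft.reactions
    )
    metabolites = {
        m.full_id: m
        for m in (
            draft.metabolites.values()
            if isinstance(draft.metabolites, dict)
            else draft.metabolites
        )
    }
    genes = {
        g.id: g
        for g in (draft.genes.values() if isinstance(draft.genes, dict) else draft.genes)
    }
    model_id = getattr(draft, "model_id", None) or getattr(draft, "draft_id", "draft")

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model_id))
    sbml_model.setName(getattr(draft, "organism", "") or model_id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    for comp_id in sorted({m.compartment for m in metabolites.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for full_id in sorted(metabolites):
        met = metabolites[full_id]
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", full_id))
        sp.setName(met.name or full_id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(met.formula)

    label_to_sid: Dict[str, str] = {}
    for gid in sorted(genes):
        gp = mplug.createGeneProduct()
        sid = _sid("G_", gid)
        gp.setId(sid)
        gp.setLabel(gid)
        label_to_sid[gid] = sid

    bound_params: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in sorted(reactions, key=lambda r: r.id):
        rx = sbml_model.createReaction()
        rx.setId(_sid("R_", rxn.id))
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for met, coeff in sorted(
            rxn.stoichiometry.items(), key=lambda kv: kv[0].full_id
        ):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_sid("M_", met.full_id))
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        rule = rxn.gpr_rule
        if rule is not None:
            missing = gpr_mod.genes(rule) - label_to_sid.keys()
            if missing:
                raise ModelIntegrityError(
                    f"reaction {rxn.id!r} GPR references genes absent from the "
                    f"draft: {sorted(missing)!r}"
                )
            gpa = rplug.createGeneProductAssociation()
            _rule_to_association(gpa, rule, label_to_sid)

    if doc.checkInternalConsistency() > 0:
        errors = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if errors:
            raise ModelFormatError(f"SBML document inconsistent: {errors}")
    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# FASTA and tabular hits
# ---------------------------------------------------------------------------

def read_proteome_fasta(
    path: Union[str, Path], model_of_origin: str = ""
) -> Dict[str, Gene]:
    """Read an amino-acid FASTA into an ordered id -> :class:`Gene` mapping.

    Record ids are the token before the first whitespace, case-sensitive.
    Duplicate ids and empty files are rejected.
    """
    genes: Dict[str, Gene] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in genes:
                raise ModelFormatError(
                    f"{path}: duplicate FASTA record id {record.id!r}"
                )
            genes[record.id] = Gene(
                id=record.id,
                protein_sequence=str(record.seq).upper().rstrip("*"),
                model_of_origin=model_of_origin,
            )
    if not genes:
        raise ModelFormatError(f"{path}: no FASTA records found")
    return genes


def read_hits_table(path: Union[str, Path]) -> List[HomologyHit]:
    """Read a tab-separated hits file: query, subject, percent identity,
    alignment length, e-value, bit score, query length."""
    hits: List[HomologyHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ModelFormatError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, s, pident, length, evalue, bits, qlen = fields
            try:
                hit = HomologyHit(
                    query_id=q,
                    subject_id=s,
                    identity_pct=float(pident),
                    aln_length=int(length),
                    evalue=float(evalue),
                    bitscore=float(bits),
                    query_length=int(qlen),
                )
            except ValueError as exc:
                raise ModelFormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits
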