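"""Model/sequence/hit-table IO: JSON, SBML+FBC, FASTA, tabular hits."""

import gzip
import json
import random
import warnings
from fractions import Fraction

import pytest

from biggdraft import gpr, model_io
from biggdraft.model_io import (
    ModelFormatError,
    ModelIntegrityError,
    read_hits_table,
    read_proteome_fasta,
    read_template_json,
    read_template_sbml,
    split_compartment,
    write_draft_sbml,
    write_template_json,
)

from oracle_utils import all_assignments

MINIMAL_MODEL = {
    "id": "mini",
    "metabolites": [
        {"id": "glc__D_c", "compartment": "c"},
        {"id": "g6p_c", "compartment": "c"},
    ],
    "genes": [{"id": "g1"}],
    "reactions": [
        {
            "id": "HEX1",
            "metabolites": {"glc__D_c": -1, "g6p_c": 1},
            "lower_bound": 0,
            "upper_bound": 1000,
            "gene_reaction_rule": "g1",
        }
    ],
}


class TestJson:
    def test_minimal_model(self, tmp_path):
        path = tmp_path / "mini.json"
        path.write_text(json.dumps(MINIMAL_MODEL))
        model = read_template_json(path)
        assert len(model.reactions) == 1 and len(model.genes) == 1
        rxn = model.reactions["HEX1"]
        assert rxn.gpr_rule == gpr.GeneRef("g1")
        assert not rxn.reversible
        # last-underscore split keeps BiGG double-underscore base ids intact
        assert model.metabolites["glc__D_c"].base_id == "glc__D"

    def test_undeclared_metabolite_is_integrity_error(self, tmp_path):
        raw = json.loads(json.dumps(MINIMAL_MODEL))
        raw["reactions"][0]["metabolites"]["missing_c"] = 1
        path = tmp_path / "broken.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(ModelIntegrityError, match="missing_c"):
            read_template_json(path)

    def test_malformed_json_and_missing_key(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ModelFormatError, match="malformed JSON"):
            read_template_json(bad)
        nokey = tmp_path / "nokey.json"
        nokey.write_text(json.dumps({"metabolites": [], "reactions": []}))
        with pytest.raises(ModelFormatError, match="genes"):
            read_template_json(nokey)

    def test_fixture_roundtrip_matches_generator_record(self, tmp_path, bundle):
        # write/read every generated template and compare field for field
        for template in bundle.templates:
            path = tmp_path / f"{template.model_id}.json"
            write_template_json(template, path)
            back = read_template_json(path)
            assert back.model_id == template.model_id
            assert set(back.reactions) == set(template.reactions)
            assert set(back.genes) == set(template.genes)
            for rid, rxn in template.reactions.items():
                loaded = back.reactions[rid]
                assert {m.full_id: c for m, c in loaded.stoichiometry.items()} == {
                    m.full_id: c for m, c in rxn.stoichiometry.items()
                }
                assert loaded.gpr_string == rxn.gpr_string
                assert loaded.reversible == rxn.reversible
            for gid, gene in template.genes.items():
                assert back.genes[gid].protein_sequence == gene.protein_sequence

    def test_reading_twice_is_deterministic(self, tmp_path, bundle):
        path = tmp_path / "t.json"
        write_template_json(bundle.templates[0], path)
        assert read_template_json(path) == read_template_json(path)


class TestSbml:
    def test_write_read_roundtrip_preserves_content(self, tmp_path, bundle):
        template = bundle.templates[0]
        path = tmp_path / "template.xml"
        write_draft_sbml(template, path)
        back = read_template_sbml(path)
        assert set(back.reactions) == set(template.reactions)
        for rid, rxn in template.reactions.items():
            loaded = back.reactions[rid]
            # stoichiometry must survive as exact rationals
            assert {m.full_id: c for m, c in loaded.stoichiometry.items()} == {
                m.full_id: c for m, c in rxn.stoichiometry.items()
            }
            assert loaded.reversible == rxn.reversible
            # GPR strings may differ syntactically but truth tables must not
            rule, rule_back = rxn.gpr_rule, loaded.gpr_rule
            assert (rule is None) == (rule_back is None)
            if rule is not None:
                for present in all_assignments(gpr.genes(rule)):
                    assert gpr.evaluate(rule, present) == gpr.evaluate(
                        rule_back, present
                    )

    def test_species_compartment_suffix_convention(self, tmp_path, bundle):
        path = tmp_path / "t.xml"
        write_draft_sbml(bundle.templates[0], path)
        back = read_template_sbml(path)
        met = next(iter(back.metabolites.values()))
        assert met.full_id == f"{met.base_id}_{met.compartment}"
        assert met.compartment == "c"

    def test_fbc_and_maps_to_conjunction(self, tmp_path):
        model = model_io.TemplateModel(model_id="two")
        a = model_io.Metabolite(base_id="a", compartment="c")
        b = model_io.Metabolite(base_id="b", compartment="c")
        model.metabolites = {m.full_id: m for m in (a, b)}
        model.genes = {"g1": model_io.Gene(id="g1"), "g2": model_io.Gene(id="g2")}
        model.reactions["RX"] = model_io.Reaction(
            id="RX",
            stoichiometry={a: Fraction(-1), b: Fraction(1)},
            gpr_string="g1 and g2",
        )
        path = tmp_path / "two.xml"
        write_draft_sbml(model, path)
        rule = read_template_sbml(path).reactions["RX"].gpr_rule
        assert rule == gpr.And((gpr.GeneRef("g1"), gpr.GeneRef("g2")))

    def test_missing_gene_association_warns(self, tmp_path):
        model = model_io.TemplateModel(model_id="nogpr")
        a = model_io.Metabolite(base_id="a", compartment="c")
        b = model_io.Metabolite(base_id="b", compartment="c")
        model.metabolites = {m.full_id: m for m in (a, b)}
        model.reactions["RX"] = model_io.Reaction(
            id="RX", stoichiometry={a: Fraction(-1), b: Fraction(1)}
        )
        path = tmp_path / "nogpr.xml"
        write_draft_sbml(model, path)
        with pytest.warns(UserWarning, match="no FBC gene association"):
            back = read_template_sbml(path)
        assert back.reactions["RX"].gpr_rule is None

    def test_cobra_reads_written_sbml(self, tmp_path, bundle):
        # independent oracle: cobrapy must agree on counts and GPR truth tables
        cobra = pytest.importorskip("cobra")
        template = bundle.templates[0]
        path = tmp_path / "t.xml"
        write_draft_sbml(template, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(template.reactions)
        assert len(cm.genes) == len(template.genes)
        rng = random.Random(1)
        for rxn in list(template.reactions.values())[:10]:
            rule = rxn.gpr_rule
            if rule is None:
                continue
            cobra_gpr = cm.reactions.get_by_id(rxn.id).gpr
            genes = sorted(gpr.genes(rule))
            for _ in range(8):
                present = {g for g in genes if rng.random() < 0.5}
                knockouts = [g for g in genes if g not in present]
                assert cobra_gpr.eval(knockouts) == gpr.evaluate(rule, present)


class TestFastaAndHits:
    def test_two_record_fasta(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">p1 desc\nMKV\n>p2\nACDEF\n")
        genes = read_proteome_fasta(path)
        assert list(genes) == ["p1", "p2"]
        assert genes["p2"].protein_sequence == "ACDEF"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.faa"
        path.write_text(">g1\nMKV\n>g1\nMKL\n")
        with pytest.raises(ModelFormatError, match="g1"):
            read_proteome_fasta(path)

    def test_empty_fasta_rejected(self, tmp_path):
        path = tmp_path / "empty.faa"
        path.write_text("")
        with pytest.raises(ModelFormatError, match="no FASTA records"):
            read_proteome_fasta(path)

    def test_fixture_proteome_matches_generator(self, bundle_dir):
        out, bundle = bundle_dir
        genes = read_proteome_fasta(out / "query.faa")
        assert len(genes) == len(bundle.query_proteome)
        total = sum(len(g.protein_sequence) for g in genes.values())
        assert total == bundle.truth.query_residue_total

    def test_gzip_transparency(self, tmp_path):
        path = tmp_path / "p.faa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">p1\nMKV\n")
        assert read_proteome_fasta(path)["p1"].protein_sequence == "MKV"

    def test_hits_table_valid_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t98.5\t80\t1e-30\t120.0\t100\n")
        (hit,) = read_hits_table(path)
        assert hit.bitscore == 120.0 and hit.query_length == 100
        assert hit.query_coverage == pytest.approx(0.8)

    def test_bad_evalue_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t98.5\t80\t1e-30\t120.0\t100\n"
            "q2\ts2\t97.0\t70\tnot-a-number\t90.0\t100\n"
        )
        with pytest.raises(ModelFormatError, match=":2:"):
            read_hits_table(path)

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t98.5\n")
        with pytest.raises(ModelFormatError, match="7"):
            read_hits_table(path)

    def test_large_table_matches_generator(self, tmp_path):
        rng = random.Random(17)
        rows, score_sum = [], 0.0
        for i in range(500):
            score = round(rng.uniform(40, 300), 1)
            score_sum += score
            rows.append(f"q{i}\ts{rng.randrange(50)}\t90.0\t80\t1e-40\t{score}\t100")
        path = tmp_path / "big.tsv"
        path.write_text("\n".join(rows) + "\n")
        hits = read_hits_table(path)
        assert len(hits) == 500
        assert sum(h.bitscore for h in hits) == pytest.approx(score_sum)


def test_split_compartment():
    assert split_compartment("glc__D_c") == ("glc__D", "c")
    assert split_compartment("atp_p") == ("atp", "p")
    with pytest.raises(ModelFormatError):
        split_compartment("noseparator")
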