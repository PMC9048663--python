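import pytest

import pathcurator as pc
from pathcurator.model_core import Direction
from pathcurator.retrieval import (
    ParseError,
    PathwayTemplate,
    RetrievalError,
    cache_path,
    make_fetcher,
)

KEGG_REACTION = """\
ENTRY       R00299                      Reaction
NAME        ATP:D-glucose 6-phosphotransferase
EQUATION    C00002 + C00031 <=> C00008 + C00092
ENZYME      2.7.1.1         2.7.1.2
///
"""

KEGG_COMPOUND = """\
ENTRY       C00031                      Compound
NAME        D-Glucose
FORMULA     C6H12O6
///
"""

KEGG_MODULE = """\
ENTRY       M00001                      Module
NAME        toy glycolysis segment
REACTION    R00299 R00756 R01068
///
"""

BIOCYC_REACTION = """\
<ptools-xml><Reaction frameid='GLUCOKIN-RXN'>
<left><Compound frameid='ATP'/></left>
<left><Compound frameid='GLC'/></left>
<right><Compound frameid='ADP'/></right>
<right><Compound frameid='GLC-6-P'/></right>
<reaction-direction>LEFT-TO-RIGHT</reaction-direction>
</Reaction></ptools-xml>
"""

BIGG_REACTION = """\
{"bigg_id": "HEX1", "name": "hexokinase", "pseudoreaction": false,
 "metabolites": [
   {"bigg_id": "atp", "compartment_bigg_id": "c", "stoichiometry": -1},
   {"bigg_id": "glc__D", "compartment_bigg_id": "c", "stoichiometry": -1},
   {"bigg_id": "adp", "compartment_bigg_id": "c", "stoichiometry": 1},
   {"bigg_id": "g6p", "compartment_bigg_id": "c", "stoichiometry": 1},
   {"bigg_id": "h", "compartment_bigg_id": "c", "stoichiometry": 1}]}
"""


class TestParseKegg:
    def test_reaction_equation(self):
        rec = pc.parse_kegg(KEGG_REACTION)
        assert rec.kind == "reaction" and rec.identifier == "R00299"
        assert rec.parsed.stoichiometry == {
            "C00002": -1, "C00031": -1, "C00008": 1, "C00092": 1}
        assert rec.parsed.direction == Direction.REVERSIBLE
        assert rec.parsed.cross_refs["ec-code"] == ["2.7.1.1", "2.7.1.2"]

    def test_compound_formula(self):
        rec = pc.parse_kegg(KEGG_COMPOUND)
        assert rec.kind == "metabolite"
        assert rec.parsed.formula.element_counts == {"C": 6, "H": 12, "O": 6}

    def test_coefficient_tokens(self):
        text = ("ENTRY       R1   Reaction\n"
                "EQUATION    2 C00001 + C00002 <=> C00009\n///\n")
        rec = pc.parse_kegg(text)
        assert rec.parsed.stoichiometry == {
            "C00001": -2, "C00002": -1, "C00009": 1}

    def test_module_reaction_order(self):
        rec = pc.parse_kegg(KEGG_MODULE)
        assert isinstance(rec.parsed, PathwayTemplate)
        assert rec.parsed.reaction_identifiers == \
            ["R00299", "R00756", "R01068"]

    @pytest.mark.parametrize("text, match", [
        ("ENTRY       R1   Reaction\nEQUATION    A <=> B\n", "terminator"),
        ("NAME        x\n///\n", "ENTRY"),
        ("ENTRY       R1   Reaction\n"
         "EQUATION    A + 2(n) <=> B\n///\n", r"2\(n\)"),
    ])
    def test_parse_errors(self, text, match):
        with pytest.raises(ParseError, match=match):
            pc.parse_kegg(text)


class TestParseBiocyc:
    def test_reaction(self):
        rec = pc.parse_biocyc(BIOCYC_REACTION)
        assert rec.kind == "reaction" and rec.identifier == "GLUCOKIN-RXN"
        assert rec.parsed.direction == Direction.FORWARD
        assert rec.parsed.stoichiometry == {
            "ATP": -1, "GLC": -1, "ADP": 1, "GLC-6-P": 1}

    @pytest.mark.parametrize("literal, expected", [
        ("REVERSIBLE", Direction.REVERSIBLE),
        ("PHYSIOL-LEFT-TO-RIGHT", Direction.FORWARD),
        ("PHYSIOL-RIGHT-TO-LEFT", Direction.BACKWARD),
    ])
    def test_direction_mapping(self, literal, expected):
        text = BIOCYC_REACTION.replace("LEFT-TO-RIGHT", literal)
        assert pc.parse_biocyc(text).parsed.direction == expected

    def test_coefficient_child_sign(self):
        text = BIOCYC_REACTION.replace(
            "<left><Compound frameid='ATP'/></left>",
            "<left><Compound frameid='ATP'/>"
            "<coefficient>2</coefficient></left>")
        assert pc.parse_biocyc(text).parsed.stoichiometry["ATP"] == -2

    def test_unknown_direction_rejected(self):
        text = BIOCYC_REACTION.replace("LEFT-TO-RIGHT", "SIDEWAYS")
        with pytest.raises(ParseError, match="SIDEWAYS"):
            pc.parse_biocyc(text)

    def test_empty_side_rejected(self):
        text = ("<ptools-xml><Reaction frameid='R'>"
                "<right><Compound frameid='B'/></right>"
                "<reaction-direction>REVERSIBLE</reaction-direction>"
                "</Reaction></ptools-xml>")
        with pytest.raises(ParseError, match="left"):
            pc.parse_biocyc(text)

    def test_compound_formula_and_charge(self):
        text = ("<ptools-xml><Compound frameid='GLC'>"
                "<cml><molecule formalCharge='-1'>"
                "<formula concise='C 6 H 12 O 6'/></molecule></cml>"
                "</Compound></ptools-xml>")
        rec = pc.parse_biocyc(text)
        assert rec.parsed.formula.element_counts == {"C": 6, "H": 12, "O": 6}
        assert rec.parsed.charge == -1


class TestParseBigg:
    def test_reaction(self):
        rec = pc.parse_bigg(BIGG_REACTION)
        assert rec.kind == "reaction" and rec.identifier == "HEX1"
        assert len(rec.parsed.participants) == 5
        assert all(p.compartment == "c" for p in rec.parsed.participants)

    def test_metabolite_first_formula_and_charge(self):
        text = ('{"bigg_id": "glc__D", "name": "D-glucose", '
                '"formulae": ["C6H12O6"], "charges": [0]}')
        rec = pc.parse_bigg(text)
        assert rec.parsed.formula.element_counts == {"C": 6, "H": 12, "O": 6}
        assert rec.parsed.charge == 0

    def test_pseudoreaction_rejected(self):
        text = ('{"bigg_id": "EX_glc", "pseudoreaction": true, '
                '"metabolites": [{"bigg_id": "glc__D", '
                '"compartment_bigg_id": "e", "stoichiometry": -1}]}')
        with pytest.raises(ParseError, match="pseudoreaction"):
            pc.parse_bigg(text)


class TestParseUserTable:
    def test_reaction_line(self):
        recs = pc.parse_user_table(
            "R SHKK, shikimate kinase | "
            "1 atp_c, 1 skm_c -> 1 adp_c, 1 skm6p_c")
        parsed = recs[0].parsed
        assert parsed.direction == Direction.FORWARD
        assert parsed.stoichiometry == {
            "atp_c": -1, "skm_c": -1, "adp_c": 1, "skm6p_c": 1}
        assert parsed.bounds is None  # defaults applied at conversion

    def test_metabolite_line(self):
        recs = pc.parse_user_table("M skm_c, shikimate, c, C7H10O5, -1")
        parsed = recs[0].parsed
        assert parsed.formula.element_counts == {"C": 7, "H": 10, "O": 5}
        assert parsed.charge == -1 and parsed.compartment == "c"

    def test_comments_arrows_and_bounds(self):
        text = ("# a comment\n"
                "R A1 | b_c <-> c_c | -5, 5\n"
                "R A2 | b_c <- c_c\n")
        recs = pc.parse_user_table(text)
        assert recs[0].parsed.direction == Direction.REVERSIBLE
        assert recs[0].parsed.bounds == (-5, 5)
        assert recs[1].parsed.direction == Direction.BACKWARD

    def test_empty_side_error_cites_line(self):
        with pytest.raises(ParseError, match="line 1"):
            pc.parse_user_table("R BAD | ->")

    def test_duplicate_ids_rejected(self):
        text = "M a_c, a, c, -, -\nM a_c, again, c, -, -\n"
        with pytest.raises(ParseError, match="duplicate"):
            pc.parse_user_table(text)


class TestFetchRecord:
    def test_cache_hit_from_disk(self, fixture_cache):
        rec = pc.fetch_record("kegg", "R0", "reaction", fixture_cache,
                              offline=True)
        assert rec.parsed.stoichiometry == {"M0": -1, "M1": 1}

    def test_offline_miss_names_path(self, tmp_path):
        expected = cache_path(tmp_path, "kegg", "reaction", "R99999")
        with pytest.raises(RetrievalError, match="R99999.txt"):
            pc.fetch_record("kegg", "R99999", "reaction", tmp_path,
                            offline=True)
        assert str(expected).endswith("kegg/reaction/R99999.txt")

    def test_second_fetch_does_not_invoke_provider(self, tmp_path, provider):
        pc.fetch_record("kegg", "R0", "reaction", tmp_path,
                        provider=provider)
        assert provider.calls == 1
        pc.fetch_record("kegg", "R0", "reaction", tmp_path,
                        provider=provider)
        assert provider.calls == 1  # served from cache

    def test_cached_raw_is_verbatim(self, tmp_path, provider, chain_model):
        records = pc.generate_fixture_records(chain_model)
        rec = pc.fetch_record("biocyc", "R1", "reaction", tmp_path,
                              provider=provider)
        assert rec.raw == records[("biocyc", "reaction", "R1")]
        again = pc.fetch_record("biocyc", "R1", "reaction", tmp_path,
                                offline=True)
        assert again.raw == rec.raw


class TestCreateObject:
    def test_stub_metabolites_created(self, tmp_path, provider):
        fetcher = make_fetcher(tmp_path, provider=provider)
        model = pc.Model("m")
        model.compartments["c"] = "c"
        rxn = pc.create_object(fetcher("kegg", "reaction", "R0"), "c",
                               model, fetcher)
        assert rxn.stoichiometry == {"M0_c": -1, "M1_c": 1}
        assert set(model.metabolites) == {"M0_c", "M1_c"}
        assert model.metabolites["M0_c"].formula is not None

    def test_cross_reference_resolution_returns_existing(self, tmp_path,
                                                         provider):
        fetcher = make_fetcher(tmp_path, provider=provider)
        model = pc.Model("m")
        model.compartments["c"] = "c"
        rxn = pc.create_object(fetcher("kegg", "reaction", "R0"), "c",
                               model, fetcher)
        model.add_reaction(rxn)
        again = pc.create_object(fetcher("kegg", "reaction", "R0"), "c",
                                 model, fetcher)
        assert again is rxn

    def test_pathway_conversion(self, tmp_path, provider):
        fetcher = make_fetcher(tmp_path, provider=provider)
        model = pc.Model("m")
        model.compartments["c"] = "c"
        pw = pc.create_object(fetcher("kegg", "pathway", "TOYPATH"), "c",
                              model, fetcher)
        assert pw.reaction_ids == ["R0", "R1", "R2"]
        assert len(pw.staged_reactions) == 3

    def test_unresolvable_participant_lists_missing(self, tmp_path):
        empty = pc.DictProvider({("kegg", "reaction", "RX"):
                                 "ENTRY       RX   Reaction\n"
                                 "EQUATION    C09999 <=> C08888\n///\n"})
        fetcher = make_fetcher(tmp_path, provider=empty)
        model = pc.Model("m")
        model.compartments["c"] = "c"
        with pytest.raises(RetrievalError, match="C09999"):
            pc.create_object(fetcher("kegg", "reaction", "RX"), "c",
                             model, fetcher)


class TestDialectConsistency:
    def test_same_network_from_all_dialects(self, tmp_path, chain_model):
        """KEGG, BioCyc and BiGG fixtures for one toy network convert to
        stoichiometrically identical models (up to id namespace)."""
        provider = pc.fixture_provider(chain_model)
        matrices = {}
        for src in ("kegg", "biocyc", "bigg"):
            fetcher = make_fetcher(tmp_path / src, provider=provider)
            model = pc.Model(src)
            model.compartments["c"] = "c"
            if src == "bigg":  # BiGG has no pathway record type
                entities = [
                    pc.create_object(fetcher(src, "reaction", rid), "c",
                                     model, fetcher)
                    for rid in ("R0", "R1", "R2")]
            else:
                entities = [pc.create_object(
                    fetcher(src, "pathway", "TOYPATH"), "c", model, fetcher)]
            pc.run_curation(model, entities)
            S = pc.build_stoichiometric_matrix(model)
            matrices[src] = (S.metabolite_ids, S.reaction_ids,
                             S.matrix.tolist())
        assert matrices["kegg"] == matrices["biocyc"] == matrices["bigg"]

    def test_parse_is_deterministic(self, chain_model):
        records = pc.generate_fixture_records(chain_model)
        parsers = {"kegg": pc.parse_kegg, "biocyc": pc.parse_biocyc,
                   "bigg": pc.parse_bigg}
        for (src, _, _), text in records.items():
            first, second = parsers[src](text), parsers[src](text)
            assert first.parsed == second.parsed
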