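"""Decision-engine tests, including the encoded study evidence.

The study fixture encodes 15 barcode OTUs in three clades plus one
morphology-only taxon; the engine must reproduce the published
delimitation: ten species in the focal collection, with the four
*B. claviformis* population OTUs lumped, the voucher-less Bali OTU held
provisional, and cryptic non-sister lineages kept apart on topology.
"""

import numpy as np
import pytest

from bivesdelim.delimit import (CriteriaConfig, DelimitError, EvidenceTable,
                                delimit_species, explain_decision)
from bivesdelim.distance import DistanceMatrix
from bivesdelim.evidence import DistinctionMatrix, HostRecord
from bivesdelim.phylo import parse_newick
from bivesdelim.study_fixture import CRYPTIC_GROUPS, build_bivesicula_fixture


def simple_evidence(newick, morph_pairs, host_families, **kw):
    """Small hand-built evidence table.

    ``morph_pairs``: dict (a, b) -> flag; unset pairs default distinct.
    ``host_families``: dict otu -> list of families.
    """
    tree = parse_newick(newick)
    otus = sorted(l.taxon.label for l in tree.leaf_node_iter())
    dmx = DistinctionMatrix(tuple(otus) + tuple(kw.get("morphospecies", ())))
    for i, a in enumerate(dmx.labels):
        for b in dmx.labels[i + 1:]:
            dmx.set_morphology(a, b, "distinct")
    for (a, b), flag in morph_pairs.items():
        dmx.set_morphology(a, b, flag)
    records = tuple(
        HostRecord(label=o, host_species=f"{fam} sp.", host_family=fam,
                   n_infected=1, n_examined=1)
        for o, fams in host_families.items() for fam in fams)
    dmx.fill_biology_from_hosts(records)
    return EvidenceTable(otus=tuple(otus), guide_tree=tree, distinctions=dmx,
                         host_records=records, **kw)


class TestCriteriaBranches:
    def test_compatible_sisters_merge(self):
        ev = simple_evidence("(A,B,C);",
                            {("A", "B"): "indistinguishable"},
                            {"A": ["Serranidae"], "B": ["Serranidae"],
                             "C": ["Serranidae"]})
        res = delimit_species(ev)
        assert {h.members for h in res.hypotheses} == {("A", "B"), ("C",)}

    def test_disjoint_hosts_split_sisters_citing_biology(self):
        ev = simple_evidence("(A,B,C);",
                            {("A", "B"): "indistinguishable"},
                            {"A": ["Apogonidae"], "B": ["Pomacentridae"],
                             "C": ["Serranidae"]})
        res = delimit_species(ev)
        assert len(res.hypotheses) == 3
        hyp_a = res.find("A")
        entry = next(j for j in hyp_a.justification if j.other == "B")
        assert entry.basis == "biology"

    def test_cryptic_non_sisters_split_on_topology(self):
        """Two cryptic lineages separated by a distinct species stay apart."""
        ev = simple_evidence(
            "(clav,(sheni,obo),out);",
            {("clav", "sheni"): "indistinguishable"},
            {o: ["Serranidae"] for o in ("clav", "sheni", "obo", "out")})
        res = delimit_species(ev)
        assert len(res.hypotheses) == 4
        entry = next(j for j in res.find("clav").justification
                     if j.other == "sheni")
        assert entry.basis == "topology"
        assert "separated by another clearly distinct species" in entry.detail

    def test_unknown_morphology_blocks_merge_and_is_provisional(self):
        ev = simple_evidence("(A,B,C);",
                            {("A", "B"): "unknown", ("A", "C"): "unknown"},
                            {o: ["Serranidae"] for o in "ABC"})
        res = delimit_species(ev)
        hyp = res.find("A")
        assert hyp.status == "provisional_sequence_only"
        assert len(res.hypotheses) == 3

    def test_merge_distance_ceiling_vetoes_lump(self):
        host = {o: ["Serranidae"] for o in "ABC"}
        ev = simple_evidence("((A,B),C);",
                             {("A", "B"): "indistinguishable"}, host)
        values = np.array([[0, 25, 60], [25, 0, 60], [60, 60, 0]], float)
        ev.otu_distances = DistanceMatrix(
            ("A", "B", "C"), values, np.full((3, 3), 474, dtype=np.int64))
        merged = delimit_species(ev)
        assert any(len(h.members) == 2 for h in merged.hypotheses)
        vetoed = delimit_species(
            ev, CriteriaConfig(merge_distance_ceiling=20))
        assert all(len(h.members) == 1 for h in vetoed.hypotheses)
        assert any("vetoed" in w for w in vetoed.warnings)

    def test_morphospecies_indistinguishable_from_otu_not_appended(self):
        ev = simple_evidence(
            "(A,B,C);", {("M", "A"): "indistinguishable"},
            {o: ["Serranidae"] for o in "ABC"}, morphospecies=("M",))
        res = delimit_species(ev)
        assert all(h.status != "unsequenced_morphospecies"
                   for h in res.hypotheses)
        assert any("not appended" in w for w in res.warnings)


@pytest.fixture(scope="module")
def result(study_fixture):
    return delimit_species(study_fixture.evidence)


class TestStudyFixtureDelimitation:
    def test_ten_species_in_the_collection(self, result):
        assert result.n_species == 10

    def test_claviformis_population_otus_lumped(self, result):
        hyp = result.find("OTU4")
        assert hyp.members == ("OTU4", "OTU5", "OTU6", "OTU7")
        assert hyp.name == "B. claviformis"

    def test_gymnothoracis_population_otus_lumped(self, result):
        assert result.find("OTU12").members == ("OTU12", "OTU13")

    def test_bali_otu_is_provisional(self, result):
        hyp = result.find("OTU9")
        assert hyp.status == "provisional_sequence_only"
        assert hyp.members == ("OTU9",)

    def test_one_unsequenced_morphospecies(self, result):
        morpho = [h for h in result.hypotheses
                  if h.status == "unsequenced_morphospecies"]
        assert len(morpho) == 1
        assert morpho[0].name == "B. nana"

    def test_eight_named_species(self, result):
        named = [h for h in result.hypotheses if h.status == "named"]
        assert len(named) == 8

    def test_published_species_composition(self, result):
        by_name = {}
        for h in result.hypotheses:
            if h.members:
                by_name[h.name] = set(h.members)
        assert by_name == {
            "B. sheni": {"OTU1"},
            "B. obovata": {"OTU2"},
            "B. polynesiensis": {"OTU3"},
            "B. claviformis": {"OTU4", "OTU5", "OTU6", "OTU7"},
            "B. cephalopholicola": {"OTU8"},
            "Bivesicula sp. (Bali)": {"OTU9"},
            "B. novaecaledoniensis": {"OTU10"},
            "B. palauensis": {"OTU11"},
            "B. gymnothoracis": {"OTU12", "OTU13"},
        }

    def test_comparative_taxa_reported_separately(self, result):
        names = {h.name for h in result.comparative_taxa}
        assert names == {"B. neglecta", "B. unexpecta"}
        assert all(h.comparative for h in result.comparative_taxa)

    def test_multi_otu_species_are_guide_tree_clades(self, result,
                                                     study_fixture):
        from bivesdelim.phylo import is_bipartition_clade, restrict_tree
        ev = study_fixture.evidence
        focal = set(ev.otus) - ev.comparative
        sub = restrict_tree(ev.guide_tree, focal)
        for hyp in result.hypotheses:
            if len(hyp.members) > 1:
                assert is_bipartition_clade(sub, hyp.members)

    def test_otu_input_order_does_not_matter(self, study_fixture):
        ev = study_fixture.evidence
        reordered = EvidenceTable(
            otus=tuple(reversed(ev.otus)), guide_tree=ev.guide_tree,
            distinctions=ev.distinctions, host_records=ev.host_records,
            morphospecies=ev.morphospecies, comparative=ev.comparative,
            name_hints=ev.name_hints)
        a = delimit_species(ev)
        b = delimit_species(reordered)
        assert {frozenset(h.members) for h in a.hypotheses} == \
            {frozenset(h.members) for h in b.hypotheses}

    def test_flipping_any_cryptic_pair_never_decreases_species_count(self):
        base = delimit_species(build_bivesicula_fixture().evidence).n_species
        flippable = [(a, b) for group in CRYPTIC_GROUPS
                     for i, a in enumerate(group) for b in group[i + 1:]]
        for a, b in flippable:
            fx = build_bivesicula_fixture()
            fx.evidence.distinctions.set_morphology(a, b, "distinct")
            assert delimit_species(fx.evidence).n_species >= base

    def test_sheni_vs_claviformis_trace_cites_topology(self, result,
                                                       study_fixture):
        text = explain_decision(result, "B. sheni", "B. claviformis",
                                ev=study_fixture.evidence)
        assert "topology" in text
        assert "do not form an exclusive clade" in text

    def test_neglecta_vs_unexpecta_trace_cites_morphology_and_biology(
            self, result):
        text = explain_decision(result, "B. neglecta", "B. unexpecta")
        assert "morphology" in text
        hyp = result.find("B. neglecta")
        bases = {j.basis for j in hyp.justification
                 if j.other == "B. unexpecta"}
        assert bases == {"morphology"}
        # biology is also distinct for this pair
        from bivesdelim.evidence import assess_host_distinction
        fx = build_bivesicula_fixture()
        assert assess_host_distinction(fx.evidence.host_records,
                                       "OTU14", "OTU15") == "distinct"

    def test_same_species_comparison_errors(self, result):
        with pytest.raises(DelimitError):
            explain_decision(result, "OTU4", "OTU5")

    def test_guide_tree_otu_mismatch_rejected(self, study_fixture):
        ev = study_fixture.evidence
        with pytest.raises(DelimitError):
            EvidenceTable(otus=ev.otus[:-1], guide_tree=ev.guide_tree,
                          distinctions=ev.distinctions)


class TestConfig:
    def test_defaults(self):
        cfg = CriteriaConfig()
        assert cfg.otu_threshold == 10
        assert cfg.marker_priority[0] == "cox1"
        assert cfg.biology_rule == "shared_family"
        assert cfg.merge_distance_ceiling is None

    def test_invalid_threshold_rejected(self):
        with pytest.raises(DelimitError):
            CriteriaConfig(otu_threshold=0)
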