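import pytest

from bivesdelim.evidence import (DistinctionMatrix, EvidenceError, HostRecord,
                                 MorphRecord, assess_host_distinction,
                                 derive_morphometrics, host_association_summary,
                                 plot_shape_scatter, read_host_records_csv,
                                 shape_comparison, write_host_records_csv)
from bivesdelim.synthetic_data import MorphSimSpec, simulate_morphometrics


def rec(label, family, species="sp", locality="loc"):
    return HostRecord(label=label, host_species=species, host_family=family,
                      locality=locality, n_infected=1, n_examined=1)


class TestHostDistinction:
    def test_shared_family_overlapping(self):
        records = [rec("A", "Serranidae"),
                   rec("B", "Serranidae"), rec("B", "Holocentridae")]
        assert assess_host_distinction(records, "A", "B") == "overlapping"

    def test_disjoint_families_distinct(self):
        records = [rec("A", "Apogonidae"), rec("B", "Pomacentridae")]
        assert assess_host_distinction(records, "A", "B") == "distinct"

    def test_shared_species_rule_contrast(self):
        records = [rec("A", "Serranidae", species="Epinephelus fasciatus"),
                   rec("B", "Serranidae", species="Epinephelus merra")]
        assert assess_host_distinction(records, "A", "B") == "overlapping"
        assert assess_host_distinction(records, "A", "B",
                                       rule="shared_species") == "distinct"

    def test_label_without_records_unknown(self):
        records = [rec("A", "Serranidae")]
        assert assess_host_distinction(records, "A", "B") == "unknown"

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(EvidenceError):
            HostRecord(label="A", host_species="x", host_family="Serranidae",
                       n_infected=5, n_examined=3)


class TestHostSummary:
    def test_counts_per_family_and_host(self):
        records = [rec("o1", "Serranidae", "E. fasciatus"),
                   rec("o2", "Serranidae", "E. fasciatus"),
                   rec("o2", "Holocentridae", "S. rubrum"),
                   rec("o3", "Serranidae", "E. merra")]
        smap = {"o1": "sp1", "o2": "sp2", "o3": "sp3"}
        summ = host_association_summary(records, smap)
        assert summ.species_from_host("E. fasciatus") == 2
        assert summ.species_per_family == {"Serranidae": 3, "Holocentridae": 1}

    def test_invariant_to_order_and_duplication(self):
        records = [rec("o1", "Serranidae", "E. fasciatus"),
                   rec("o2", "Holocentridae", "S. rubrum")]
        smap = {"o1": "sp1", "o2": "sp2"}
        a = host_association_summary(records, smap)
        b = host_association_summary(records[::-1] + records, smap)
        assert a.species_per_family == b.species_per_family
        assert a.species_per_host == b.species_per_host

    def test_unmapped_label_errors(self):
        with pytest.raises(EvidenceError):
            host_association_summary([rec("o1", "Serranidae")], {})

    def test_empty_records_all_counts_zero(self):
        summ = host_association_summary([], {"x": "sp"})
        assert summ.species_per_family == {}
        assert summ.species_from_host("anything") == 0

    def test_csv_roundtrip(self, tmp_path):
        records = [rec("o1", "Serranidae", "E. fasciatus", "Heron Is."),
                   rec("o2", "Holocentridae", "S. rubrum", "Lizard Is.")]
        path = tmp_path / "hosts.csv"
        write_host_records_csv(records, path)
        assert read_host_records_csv(path) == records


class TestMorphometrics:
    def make_record(self, **kw):
        defaults = dict(specimen_id="s1", label="sp", host_family="Serranidae",
                        body_length=1000.0, body_width=400.0)
        defaults.update(kw)
        return MorphRecord(**defaults)

    def test_elongation_ratio(self):
        derived = derive_morphometrics(self.make_record())
        assert derived["elongation"] == pytest.approx(2.5)

    def test_anterior_landmark_percentage(self):
        derived = derive_morphometrics(
            self.make_record(testis_from_anterior=700.0))
        assert derived["testis_pct_from_anterior"] == pytest.approx(70.0)

    def test_posterior_landmark_percentage(self):
        derived = derive_morphometrics(
            self.make_record(caeca_end_from_posterior=250.0))
        assert derived["caeca_end_pct_from_posterior"] == pytest.approx(25.0)

    def test_anterior_plus_posterior_is_exactly_100(self):
        derived = derive_morphometrics(
            self.make_record(ovary_from_posterior=317.0))
        assert derived["ovary_pct_from_posterior"] \
            + derived["ovary_pct_from_anterior"] == 100.0

    def test_vitelline_field_from_both_ends(self):
        derived = derive_morphometrics(self.make_record(
            vitelline_start_from_anterior=170.0,
            vitelline_end_from_posterior=320.0))
        assert derived["vitelline_field_um"] == pytest.approx(510.0)
        assert derived["vitelline_field_pct_body_length"] == pytest.approx(51.0)

    def test_missing_optional_metric_omitted(self):
        derived = derive_morphometrics(self.make_record())
        assert "testis_pct_from_anterior" not in derived

    def test_landmark_beyond_body_length_rejected(self):
        with pytest.raises(EvidenceError):
            self.make_record(testis_from_anterior=1500.0)


class TestShapeComparison:
    def recs(self, groups):
        out = []
        i = 0
        for family, lengths in groups.items():
            for L in lengths:
                out.append(MorphRecord(specimen_id=f"s{i}", label="sp",
                                       host_family=family,
                                       body_length=float(L), body_width=400.0))
                i += 1
        return out

    def test_exceedance_counts_match_brute_force(self):
        records = self.recs({"Serranidae": [1000, 1100],
                             "Holocentridae": [800, 900]})
        cmp = shape_comparison(records, metric="body_length")
        row = cmp.exceedance.set_index(["group_a", "group_b"])
        assert row.loc[("Serranidae", "Holocentridae"),
                       "n_a_exceeding_max_b"] == 2
        assert row.loc[("Holocentridae", "Serranidae"),
                       "n_a_exceeding_max_b"] == 0

    def test_identical_groups_no_exceedance_p_near_one(self):
        records = self.recs({"Serranidae": [1000, 1100, 1200],
                             "Holocentridae": [1000, 1100, 1200]})
        cmp = shape_comparison(records, metric="body_length")
        assert cmp.exceedance["n_a_exceeding_max_b"].sum() == 0
        assert cmp.p_value > 0.5

    def test_small_group_excluded_from_test(self):
        records = self.recs({"Serranidae": [1000, 1100],
                             "Holocentridae": [800, 900],
                             "Muraenidae": [2000]})
        cmp = shape_comparison(records, metric="body_length")
        assert cmp.p_value is not None
        assert any("Muraenidae" in n for n in cmp.notes)

    def test_host_effect_detected_on_simulated_records(self):
        records, truth = simulate_morphometrics(MorphSimSpec(seed=4))
        cmp = shape_comparison(records)
        assert cmp.p_value < 0.01
        med = cmp.group_stats.set_index("group")["median"]
        assert med["Serranidae"] > med["Holocentridae"]

    def test_scatter_plot_written(self, tmp_path):
        records, _ = simulate_morphometrics(MorphSimSpec(seed=0, n_per_group=10))
        cmp = shape_comparison(records)
        out = tmp_path / "shape.png"
        plot_shape_scatter(cmp, out)
        assert out.stat().st_size > 0


class TestDistinctionMatrix:
    def test_symmetric_and_diagonal_conventions(self):
        dmx = DistinctionMatrix(["a", "b"])
        dmx.set_morphology("a", "b", "distinct")
        assert dmx.morphology("b", "a") == "distinct"
        assert dmx.morphology("a", "a") == "indistinguishable"
        assert dmx.biology("a", "a") == "overlapping"

    def test_unset_pairs_are_unknown_and_listed(self):
        dmx = DistinctionMatrix(["a", "b", "c"])
        dmx.set_morphology("a", "b", "indistinguishable")
        assert dmx.morphology("a", "c") == "unknown"
        assert ("a", "c") in dmx.missing_pairs()

    def test_biology_filled_from_hosts(self):
        dmx = DistinctionMatrix(["a", "b"])
        dmx.fill_biology_from_hosts([rec("a", "Serranidae"),
                                     rec("b", "Apogonidae")])
        assert dmx.biology("a", "b") == "distinct"

    def test_bad_flag_rejected(self):
        dmx = DistinctionMatrix(["a", "b"])
        with pytest.raises(EvidenceError):
            dmx.set_morphology("a", "b", "similar")
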