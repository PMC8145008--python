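import pytest

from viromedeck.demarcation import (
    ContigEvidence,
    classify_demarcation,
    load_default_rules,
    merge_rules,
    read_evidence,
    summarize_discovery,
)
from viromedeck.examples import survey_contig_evidence
from viromedeck.formats_io import DemarcationRule


def evidence(**over):
    kw = dict(contig_id="c1", family="Iflaviridae", marker_identities={"capsid": 85.0})
    kw.update(over)
    return ContigEvidence(**kw)


class TestDefaultRules:
    def test_ships_exactly_the_two_families(self):
        rules = load_default_rules()
        by_family = {r.family: r for r in rules}
        assert set(by_family) == {"Alphaflexiviridae", "Iflaviridae"}
        assert by_family["Iflaviridae"].threshold_pct == 90.0
        assert by_family["Iflaviridae"].marker == "capsid"
        assert by_family["Alphaflexiviridae"].threshold_pct == 80.0
        assert by_family["Alphaflexiviridae"].marker == "capsid_or_polymerase"
        assert all(r.level == "aa" for r in rules)

    def test_user_override_wins(self):
        override = DemarcationRule("Iflaviridae", "capsid", "aa", 85.0)
        merged = merge_rules(load_default_rules(), [override])
        assert next(r for r in merged if r.family == "Iflaviridae").threshold_pct == 85.0


class TestClassify:
    def test_iflavirus_below_ninety_is_novel(self):
        verdict = classify_demarcation(evidence(marker_identities={"capsid": 85.0}))
        assert verdict.verdict == "novel_species"

    def test_iflavirus_exactly_at_threshold_is_not_novel(self):
        verdict = classify_demarcation(evidence(marker_identities={"capsid": 90.0}))
        assert verdict.verdict == "known_strain"

    def test_high_genome_identity_is_known_isolate(self):
        verdict = classify_demarcation(
            evidence(nt_genome_identity=99.5, closest_relative_id="AMV")
        )
        assert verdict.verdict == "known_isolate"

    def test_ruleless_family_low_identity_is_putative_novel(self):
        verdict = classify_demarcation(
            evidence(family="Permutotetraviridae", marker_identities={"capsid": 45.0})
        )
        assert verdict.verdict == "putative_novel_no_criterion"

    def test_ruleless_family_moderate_identity_is_indeterminate(self):
        verdict = classify_demarcation(
            evidence(family="Permutotetraviridae", marker_identities={"capsid": 75.0})
        )
        assert verdict.verdict == "indeterminate"

    def test_capsid_or_polymerase_both_semantics(self):
        ev = evidence(
            family="Alphaflexiviridae",
            marker_identities={"capsid": 70.0, "polymerase": 85.0},
        )
        assert classify_demarcation(ev).verdict == "known_strain"  # both must be below
        assert (
            classify_demarcation(ev, or_marker_semantics="either").verdict == "novel_species"
        )

    def test_missing_required_marker_is_an_error(self):
        with pytest.raises(ValueError, match="capsid"):
            classify_demarcation(evidence(marker_identities={"polymerase": 40.0}))

    def test_lowering_threshold_never_promotes_novel_to_known_isolate(self):
        ev = evidence(marker_identities={"capsid": 85.0})
        for threshold in (90.0, 87.0, 86.0, 80.0, 50.0):
            rules = [DemarcationRule("Iflaviridae", "capsid", "aa", threshold)]
            assert classify_demarcation(ev, rules).verdict != "known_isolate"

    def test_verdict_is_order_independent_pure_function(self):
        ev = evidence()
        a = classify_demarcation(ev)
        classify_demarcation(evidence(marker_identities={"capsid": 10.0}))
        b = classify_demarcation(ev)
        assert a == b


class TestSummarize:
    def test_empty_evidence_gives_zero_counts(self):
        summary = summarize_discovery([])
        assert summary["n_contigs"] == 0
        assert summary["known_isolates"] == summary["novel_total"] == 0

    def test_two_contigs_same_species_deduplicate(self):
        evs = [
            evidence(contig_id="c1", nt_genome_identity=99.0, closest_relative_id="sp1"),
            evidence(contig_id="c2", nt_genome_identity=99.9, closest_relative_id="sp1"),
        ]
        summary = summarize_discovery(evs)
        assert summary["known_isolates"] == 2
        assert summary["known_species"] == 1

    def test_survey_fixture_reproduces_published_narrative(self):
        """17 contigs: 8 known isolates of 6 species; 9 novel genomes of
        which 3 meet a family criterion, split 4 plant / 5 arthropod."""
        summary = summarize_discovery(survey_contig_evidence())
        assert summary["n_contigs"] == 17
        assert summary["known_isolates"] == 8
        assert summary["known_species"] == 6
        assert summary["novel_total"] == summary["n_contigs"] - summary["known_isolates"] == 9
        assert summary["novel_species"] == 3
        assert summary["novel_by_host_class"] == {"plant_fungus": 4, "arthropod": 5}

    def test_known_isolate_and_novel_are_mutually_exclusive(self):
        summary = summarize_discovery(survey_contig_evidence())
        verdicts = summary["verdicts"]["verdict"]
        assert (verdicts == "known_isolate").sum() + summary["novel_total"] == 17


class TestEvidenceIO:
    def test_round_trip_via_tsv(self, tmp_path):
        path = tmp_path / "ev.tsv"
        path.write_text(
            "contig_id\tfamily\thost_class\tclosest_relative_id\tnt_genome_identity\tcapsid\tpolymerase\n"
            "c1\tIflaviridae\tarthropod\trel1\t\t85.0\t\n"
            "c2\tBromoviridae\tplant_fungus\trel2\t99.5\t\t\n"
        )
        evs = read_evidence(path)
        assert evs[0].marker_identities == {"capsid": 85.0}
        assert evs[0].nt_genome_identity is None
        assert evs[1].nt_genome_identity == 99.5
        assert classify_demarcation(evs[0]).verdict == "novel_species"

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "ev.tsv"
        path.write_text("contig_id\tcapsid\nc1\t50\n")
        with pytest.raises(ValueError, match="family"):
            read_evidence(path)
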