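"""Curation battery: each rule against planted fixtures plus idempotence."""

import math

import numpy as np
import pytest

from silentbias.curation import (
    CurationConfig,
    composition_outlier_filter,
    curate,
    curate_utrs,
    dedup_within_cell,
    flag_cross_contaminants,
    longest_common_run,
    pairwise_identity,
    structural_filters,
)
from silentbias.io import GeneFamilyAlignment, TranscriptRecord
from silentbias.simulate import _mutate_at, _random_cds, curation_fixture


def _rec(tid, cell, fam, cds, cov):
    return TranscriptRecord(tid, cell, fam, cds, kmer_coverage=cov)


def _pair_fixture(rng, identity, cov_a, cov_b, cell_b="cellB"):
    """Two records in one family at a controlled identity level."""
    n_codons = 100
    a = _random_cds(rng, n_codons)
    n_diff = round((1 - identity) * len(a))
    positions = np.linspace(5, len(a) - 6, n_diff).astype(int) if n_diff else []
    b = _mutate_at(a, positions)
    records = {
        "x": _rec("x", "cellA", "f", a, cov_a),
        "y": _rec("y", cell_b, "f", b, cov_b),
    }
    aln = {"f": GeneFamilyAlignment("f", {"x": a, "y": b})}
    return records, aln


class TestPairwiseMetrics:
    def test_identity_over_shared_columns(self):
        aln = GeneFamilyAlignment("f", {"a": "ACGT--", "b": "ACTTGG"})
        assert pairwise_identity(aln, "a", "b") == pytest.approx(3 / 4)

    def test_longest_common_run(self):
        assert longest_common_run("AAACGTACGT", "TTTCGTACGA") == 6  # CGTACG
        assert longest_common_run("AAAA", "CCCC") == 0
        assert longest_common_run("", "ACGT") == 0


class TestCrossContaminants:
    def test_low_coverage_with_strong_partner_removed(self, rng):
        records, aln = _pair_fixture(rng, 0.995, cov_a=5, cov_b=40)
        records["p"] = _rec("p", "cellA", "f", _random_cds(rng, 100), 25)
        aln["f"].rows["p"] = records["p"].cds
        decisions = flag_cross_contaminants(records, aln)
        assert [d.transcript_id for d in decisions] == ["x"]
        assert decisions[0].rule_id == "xcontam_10_20"

    def test_boundary_partner_coverage_keeps_transcript(self, rng):
        records, aln = _pair_fixture(rng, 0.995, cov_a=15, cov_b=40)
        records["p"] = _rec("p", "cellA", "f", _random_cds(rng, 100), 50)
        aln["f"].rows["p"] = records["p"].cds
        # 15 < 20 but the partner is at 50, not above 100.
        assert flag_cross_contaminants(records, aln) == []

    def test_below_identity_gate_no_decision(self, rng):
        records, aln = _pair_fixture(rng, 0.98, cov_a=5, cov_b=40)
        records["p"] = _rec("p", "cellA", "f", _random_cds(rng, 100), 30)
        aln["f"].rows["p"] = records["p"].cds
        assert flag_cross_contaminants(records, aln) == []

    def test_missing_coverage_candidate_skipped(self, rng):
        records, aln = _pair_fixture(rng, 0.995, cov_a=math.nan, cov_b=40)
        records["p"] = _rec("p", "cellA", "f", _random_cds(rng, 100), 30)
        aln["f"].rows["p"] = records["p"].cds
        assert flag_cross_contaminants(records, aln) == []


class TestDedup:
    def test_high_identity_pair_removes_low_coverage(self, rng):
        records, aln = _pair_fixture(rng, 0.97, cov_a=80, cov_b=8, cell_b="cellA")
        decisions = dedup_within_cell(records, aln)
        assert [d.transcript_id for d in decisions] == ["y"]
        assert decisions[0].rule_id == "samecell_dup"

    def test_exact_run_triggers_below_identity_gate(self, rng):
        a = _random_cds(rng, 100)
        b = _random_cds(rng, 100)
        b = b[:60] + a[60:120] + b[120:]  # 60-bp planted exact run
        records = {
            "x": _rec("x", "cellA", "f", a, 80),
            "y": _rec("y", "cellA", "f", b, 8),
        }
        aln = {"f": GeneFamilyAlignment("f", {"x": a, "y": b})}
        decisions = dedup_within_cell(records, aln)
        assert [d.transcript_id for d in decisions] == ["y"]
        assert "exact run" in decisions[0].evidence

    def test_below_both_gates_kept(self, rng):
        records, aln = _pair_fixture(rng, 0.90, cov_a=80, cov_b=8, cell_b="cellA")
        assert dedup_within_cell(records, aln) == []

    def test_coverage_tie_removes_shorter(self, rng):
        a = _random_cds(rng, 100)
        b = a[:270] + "TAA"  # truncated near-copy, 91 codons
        records = {
            "long": _rec("long", "cellA", "f", a, 10),
            "shrt": _rec("shrt", "cellA", "f", b, 10),
        }
        aln = {"f": GeneFamilyAlignment("f", {"long": a, "shrt": b + "-" * 27})}
        decisions = dedup_within_cell(records, aln)
        assert [d.transcript_id for d in decisions] == ["shrt"]


class TestStructural:
    def test_short_transcript_removed(self, rng):
        base = _random_cds(rng, 100)
        short = _random_cds(rng, 12)  # 36 nt < 0.25 x mean(300,300,36)
        records = {
            "a": _rec("a", "c1", "f", base, 10),
            "b": _rec("b", "c2", "f", _random_cds(rng, 100), 10),
            "s": _rec("s", "c3", "f", short, 10),
        }
        aln = {
            "f": GeneFamilyAlignment(
                "f", {"a": base, "b": records["b"].cds, "s": short + "-" * 264}
            )
        }
        decisions = structural_filters(records, aln)
        assert {(d.transcript_id, d.rule_id) for d in decisions} == {("s", "short_25pct")}

    def test_short_same_cell_paralog_removed(self, rng):
        base = _random_cds(rng, 100)
        para = _random_cds(rng, 35)  # 105 nt < 0.5 x mean(300,300,105)
        records = {
            "a": _rec("a", "c1", "f", base, 10),
            "b": _rec("b", "c2", "f", _random_cds(rng, 100), 10),
            "p": _rec("p", "c1", "f", para, 10),
        }
        aln = {
            "f": GeneFamilyAlignment(
                "f", {"a": base, "b": records["b"].cds, "p": para + "-" * 195}
            )
        }
        decisions = structural_filters(records, aln)
        assert {(d.transcript_id, d.rule_id) for d in decisions} == {
            ("p", "paralog_50pct")
        }

    def test_best_paralog_keeps_highest_coverage(self, rng):
        a = _random_cds(rng, 100)
        b = _mutate_at(a, np.linspace(5, 290, 12).astype(int))  # 96% identical
        records = {
            "a": _rec("a", "c1", "f", a, 30),
            "b": _rec("b", "c1", "f", b, 90),
        }
        aln = {"f": GeneFamilyAlignment("f", {"a": a, "b": b})}
        decisions = structural_filters(records, aln)
        assert {(d.transcript_id, d.rule_id) for d in decisions} == {
            ("a", "best_paralog")
        }

    def test_gappy_row_removed(self, rng):
        base = _random_cds(rng, 100)
        gappy = _random_cds(rng, 65)
        records = {
            "a": _rec("a", "c1", "f", base, 10),
            "g": _rec("g", "c2", "f", gappy, 10),
        }
        aln = {
            "f": GeneFamilyAlignment("f", {"a": base, "g": gappy + "-" * 105})
        }
        decisions = structural_filters(records, aln)
        assert {(d.transcript_id, d.rule_id) for d in decisions} == {("g", "gap_30pct")}

    def test_singleton_family_only_gap_rule(self, rng):
        gappy = _random_cds(rng, 20)
        records = {"g": _rec("g", "c1", "f", gappy, 10)}
        aln = {"f": GeneFamilyAlignment("f", {"g": gappy + "-" * 60})}
        decisions = structural_filters(records, aln)
        assert [d.rule_id for d in decisions] == ["gap_30pct"]


class TestOutlierFilter:
    def _cell(self, rng, n=30):
        records, gc3s, enc = {}, {}, {}
        for i in range(n):
            tid = f"t{i:02d}"
            records[tid] = _rec(tid, "c1", f"f{i}", _random_cds(rng, 60), 50.0)
            gc3s[tid] = 0.30 + float(rng.normal(0, 0.01))
            enc[tid] = 45.0 + float(rng.normal(0, 0.5))
        return records, gc3s, enc

    def test_low_coverage_outlier_removed(self, rng):
        records, gc3s, enc = self._cell(rng)
        records["t00"].kmer_coverage = 4.0
        gc3s["t00"] = 0.9  # far beyond 3 robust-z units
        decisions = composition_outlier_filter(records, gc3s, enc)
        assert [d.transcript_id for d in decisions] == ["t00"]

    def test_high_coverage_outlier_without_paralog_kept(self, rng):
        records, gc3s, enc = self._cell(rng)
        gc3s["t00"] = 0.9
        records["t00"].kmer_coverage = 50.0
        assert composition_outlier_filter(records, gc3s, enc) == []

    def test_outlier_with_better_paralog_removed(self, rng):
        records, gc3s, enc = self._cell(rng)
        gc3s["t00"] = 0.9
        records["t00"].kmer_coverage = 50.0
        records["p"] = _rec("p", "c1", records["t00"].gene_family_id,
                            _random_cds(rng, 60), 80.0)
        gc3s["p"], enc["p"] = 0.30, 45.0
        decisions = composition_outlier_filter(records, gc3s, enc)
        assert [d.transcript_id for d in decisions] == ["t00"]

    def test_no_outliers_no_removals(self, rng):
        records, gc3s, enc = self._cell(rng)
        assert composition_outlier_filter(records, gc3s, enc) == []

    def test_small_cell_skipped(self, rng):
        records, gc3s, enc = self._cell(rng, n=10)
        gc3s["t00"] = 0.9
        records["t00"].kmer_coverage = 1.0
        assert composition_outlier_filter(records, gc3s, enc) == []


class TestUtrEligibility:
    def test_length_gates(self, rng):
        cds = _random_cds(rng, 50)
        rec = TranscriptRecord("t", "c", "f", cds, utr5="A" * 40, utr3="T" * 600)
        aln = {"f": GeneFamilyAlignment("f", {"t": cds})}
        flags, decisions = curate_utrs({"t": rec}, aln)
        assert flags["t"] == {
            "utr5": "ineligible_length",
            "utr3": "ineligible_length",
        }
        assert {d.rule_id for d in decisions} == {
            "utr_ineligible_5p",
            "utr_ineligible_3p",
        }

    def test_shared_met_and_stop_make_eligible(self, rng):
        a = _random_cds(rng, 100)
        b = _mutate_at(a, range(10, 290, 10))
        rec_a = TranscriptRecord("a", "c1", "f", a, utr5="A" * 120, utr3="T" * 200)
        rec_b = TranscriptRecord("b", "c2", "f", b)
        aln = {"f": GeneFamilyAlignment("f", {"a": a, "b": b})}
        flags, _ = curate_utrs({"a": rec_a, "b": rec_b}, aln)
        assert flags["a"] == {"utr5": "eligible", "utr3": "eligible"}

    def test_unshared_stop_column_ineligible(self, rng):
        a = _random_cds(rng, 100)
        b = _random_cds(rng, 90)
        rec_a = TranscriptRecord("a", "c1", "f", a, utr3="T" * 200)
        rec_b = TranscriptRecord("b", "c2", "f", b)
        aln = {"f": GeneFamilyAlignment("f", {"a": a, "b": b + "-" * 30})}
        flags, _ = curate_utrs({"a": rec_a, "b": rec_b}, aln)
        assert flags["a"]["utr3"] == "ineligible_no_shared_stop"

    def test_absent_utr_flagged_absent(self, rng):
        cds = _random_cds(rng, 60)
        rec = TranscriptRecord("t", "c", "f", cds)
        flags, decisions = curate_utrs({"t": rec}, {"f": GeneFamilyAlignment("f", {"t": cds})})
        assert flags["t"] == {"utr5": "absent", "utr3": "absent"}
        assert decisions == []


class TestFullBattery:
    EXPECTED_SURVIVORS = {"A1", "A6", "B2", "B3", "B4", "C1", "C2", "C3"}
    EXPECTED_REMOVALS = {
        "B1": "xcontam_10_20",
        "A2": "samecell_dup",
        "A3": "samecell_dup",
        "A4": "short_25pct",
        "A5": "paralog_50pct",
        "D1": "gap_30pct",
    }

    def test_fixture_survivor_set_exact(self):
        records, alignments = curation_fixture()
        result = curate(records, alignments)
        assert set(result.survivors) == self.EXPECTED_SURVIVORS
        removals = {
            d.transcript_id: d.rule_id
            for d in result.decisions
            if not d.rule_id.startswith("utr_")
        }
        assert removals == self.EXPECTED_REMOVALS

    def test_every_removal_is_logged(self):
        records, alignments = curation_fixture()
        result = curate(records, alignments)
        removed = set(records) - set(result.survivors)
        logged = {
            d.transcript_id for d in result.decisions if not d.rule_id.startswith("utr_")
        }
        assert removed == logged

    def test_battery_is_idempotent(self):
        records, alignments = curation_fixture()
        first = curate(records, alignments)
        pruned_aln = {f: a.subset(first.survivors) for f, a in alignments.items()}
        second = curate(first.survivors, pruned_aln)
        assert set(second.survivors) == set(first.survivors)
        assert not [d for d in second.decisions if not d.rule_id.startswith("utr_")]

    def test_utr_flags_on_fixture(self):
        records, alignments = curation_fixture()
        result = curate(records, alignments)
        assert result.utr_flags["C2"] == {"utr5": "eligible", "utr3": "eligible"}
        assert result.utr_flags["A6"] == {
            "utr5": "ineligible_length",
            "utr3": "ineligible_length",
        }
        assert result.utr_flags["B4"] == {"utr5": "absent", "utr3": "absent"}
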