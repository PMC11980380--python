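"""Codon counts, family frequencies, RSCU, ENc and usage nulls."""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import random_cds
from silentbias.codon_usage import (
    CodonCountTable,
    aa_usage,
    count_codons,
    enc_expected,
    enc_observed,
    expected_codon_usage_from_nt,
    family_frequencies,
    hypothetical_gc12,
    round_half_even_pct,
    rscu,
    stop_usage,
)

SIXFOLD = set("LSR")


def wright_enc_oracle(counts, code):
    """Step-by-step independent ENc computation (loops and dict arithmetic,
    no shared code with the implementation)."""
    by_class = {2: [], 3: [], 4: [], 6: []}
    for aa in code.amino_acids:
        synonyms = code.synonyms(aa)
        k = 6 if aa in SIXFOLD else len(synonyms)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in synonyms)
        if n < 2:
            continue
        s = 0.0
        for c in synonyms:
            p = counts.get(c, 0) / n
            s += p * p
        by_class[k].append((n * s - 1.0) / (n - 1.0))
    means = {}
    for k, vals in by_class.items():
        means[k] = sum(vals) / len(vals) if vals else None
    if means[2] is None or means[4] is None:
        return float("nan")
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0
    if means[6] is None:
        return float("nan")
    if min(means[2], means[3], means[4], means[6]) <= 0:
        return float("nan")
    enc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(enc, 61.0)


def random_count_table(rng, code, lam=8.0):
    counts = {
        c: int(rng.poisson(lam)) for c in code.sense_codons
    }
    return {c: n for c, n in counts.items() if n > 0}


class TestCounts:
    def test_simple_cds(self, code):
        t = count_codons("ATGGGGGGA", code)
        assert t.counts == {"ATG": 1, "GGG": 1, "GGA": 1}
        assert t.stop_counts == {}

    def test_terminal_stop_tallied_separately(self, code):
        t = count_codons("ATGGGGTAA", code)
        assert t.counts == {"ATG": 1, "GGG": 1}
        assert t.stop_counts == {"TAA": 1}

    def test_n_codons_excluded(self, code):
        t = count_codons("ATGGNGAAA", code)
        assert t.counts == {"ATG": 1, "AAA": 1}

    def test_pooling_is_additive(self, code, rng):
        c1 = random_cds(rng, 30, code)
        c2 = random_cds(rng, 40, code)
        merged = count_codons([c1, c2], code)
        summed = count_codons(c1, code) + count_codons(c2, code)
        assert merged.counts == summed.counts
        assert merged.stop_counts == summed.stop_counts

    def test_cell_recount_oracle(self, code, rng):
        cds_list = [random_cds(rng, int(rng.integers(10, 50)), code) for _ in range(10)]
        t = count_codons(cds_list, code)
        brute = Counter()
        for cds in cds_list:
            for i in range(0, len(cds) - 3, 3):  # skip terminal stop
                c = cds[i : i + 3]
                if code.codon_to_aa.get(c, "*") != "*":
                    brute[c] += 1
        assert t.counts == dict(brute)


class TestFamilyFrequencies:
    def test_worked_arginine_example(self, code):
        """Printed Arg usage: 3, 8 and 1213 of 1845 -> 0.16%, 0.43%, 65.75%."""
        counts = {"CGG": 3, "CGC": 8, "AGA": 1213, "CGT": 200, "CGA": 221, "AGG": 200}
        assert sum(counts.values()) == 1845
        f = family_frequencies(CodonCountTable("x", counts), code)
        assert round_half_even_pct(f["CGG"]) == 0.16
        assert round_half_even_pct(f["CGC"]) == 0.43
        assert round_half_even_pct(f["AGA"]) == 65.75

    def test_twofold_single_codon(self, code):
        f = family_frequencies(CodonCountTable("x", {"AAA": 7}), code)
        assert f["AAA"] == 1.0 and f["AAG"] == 0.0

    def test_uniform_fourfold_family(self, code):
        counts = {c: 5 for c in ("GGA", "GGC", "GGG", "GGT")}
        f = family_frequencies(CodonCountTable("x", counts), code)
        assert all(f[c] == 0.25 for c in counts)

    def test_frequencies_times_totals_reproduce_counts(self, code, rng):
        for _ in range(20):
            counts = random_count_table(rng, code)
            t = CodonCountTable("x", counts)
            f = family_frequencies(t, code)
            totals = t.aa_totals(code)
            for c, n in counts.items():
                assert f[c] * totals[code.codon_to_aa[c]] == pytest.approx(n)


class TestRscu:
    def test_uniform_fourfold_is_one(self, code):
        counts = {c: 5 for c in ("GGA", "GGC", "GGG", "GGT")}
        r = rscu(CodonCountTable("x", counts), code)
        assert all(r[c] == pytest.approx(1.0) for c in counts)

    def test_twofold_all_in_one_codon(self, code):
        r = rscu(CodonCountTable("x", {"AAA": 9}), code)
        assert r["AAA"] == 2.0 and r["AAG"] == 0.0

    def test_matches_brute_force(self, code, rng):
        for _ in range(20):
            counts = random_count_table(rng, code)
            t = CodonCountTable("x", counts)
            r = rscu(t, code)
            totals = t.aa_totals(code)
            for c in code.sense_codons:
                aa = code.codon_to_aa[c]
                if totals[aa] == 0:
                    assert math.isnan(r[c])
                else:
                    k = len(code.synonyms(aa))
                    assert r[c] == pytest.approx(k * counts.get(c, 0) / totals[aa])


class TestEncObserved:
    def test_minimal_usage_limit_is_20(self, code):
        counts = {code.synonyms(aa)[0]: 4 for aa in code.amino_acids}
        assert enc_observed(CodonCountTable("x", counts), code).enc == pytest.approx(20.0)

    def test_uniform_usage_limit_is_61(self, code):
        counts = {c: 5000 for c in code.sense_codons}
        assert enc_observed(CodonCountTable("x", counts), code).enc == pytest.approx(
            61.0, abs=0.05
        )

    def test_matches_independent_oracle_on_random_tables(self, code, rng):
        for _ in range(500):
            counts = random_count_table(rng, code, lam=float(rng.uniform(0.5, 20)))
            got = enc_observed(CodonCountTable("x", counts), code).enc
            want = wright_enc_oracle(counts, code)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_evenness_never_decreases_enc(self, code, rng):
        """Evening out one family's counts (majorization) raises ENc."""
        base = {c: 20 for c in code.sense_codons}
        skewed = dict(base)
        skewed["GGA"], skewed["GGC"] = 38, 2
        e_even = enc_observed(CodonCountTable("x", base), code).enc
        e_skew = enc_observed(CodonCountTable("x", skewed), code).enc
        assert e_even >= e_skew

    def test_missing_ile_uses_class_fallback(self, code):
        counts = {code.synonyms(aa)[0]: 4 for aa in code.amino_acids if aa != "I"}
        res = enc_observed(CodonCountTable("x", counts), code)
        assert res.enc == pytest.approx(20.0)  # F2=F4=1 -> F3 fallback 1

    def test_unestimable_returns_nan_with_reason(self, code):
        res = enc_observed(CodonCountTable("x", {"AAA": 5}), code)
        assert math.isnan(res.enc)
        assert res.reason


class TestEncExpected:
    @pytest.mark.parametrize("s,val", [(0.0, 31.0), (1.0, 32.0), (0.5, 60.5)])
    def test_closed_form_values(self, s, val):
        assert enc_expected(s) == pytest.approx(val)

    def test_maximum_near_half(self):
        grid = np.linspace(0, 1, 201)
        vals = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestExpectedUsageFromNt:
    def test_uniform_fourfold(self, code):
        f = expected_codon_usage_from_nt("G", {n: 0.25 for n in "ACGT"}, code)
        assert all(v == pytest.approx(0.25) for v in f.values())

    def test_lysine_with_no_g(self, code):
        f = expected_codon_usage_from_nt("K", {"A": 0.5, "T": 0.5, "G": 0.0, "C": 0.0}, code)
        assert f["AAA"] == pytest.approx(1.0)
        assert f["AAG"] == pytest.approx(0.0)

    def test_glycine_renormalization(self, code):
        f = expected_codon_usage_from_nt(
            "G", {"A": 0.4, "T": 0.4, "G": 0.1, "C": 0.1}, code
        )
        assert f["GGA"] == pytest.approx(0.4)
        assert f["GGT"] == pytest.approx(0.4)
        assert f["GGG"] == pytest.approx(0.1)
        assert f["GGC"] == pytest.approx(0.1)


class TestAminoAcidUsage:
    def test_pure_fymink(self, code):
        counts = {"TTT": 1, "TAT": 1, "ATG": 1, "ATT": 1, "AAT": 1, "AAA": 1}
        u = aa_usage(CodonCountTable("x", counts), code)
        assert u.fymink_frac == pytest.approx(1.0)
        assert u.garp_frac == 0.0

    def test_pure_garp(self, code):
        counts = {"GGA": 1, "GCA": 1, "CGA": 1, "CCA": 1}
        u = aa_usage(CodonCountTable("x", counts), code)
        assert u.garp_frac == pytest.approx(1.0)

    def test_matches_recount_oracle(self, code, rng):
        counts = random_count_table(rng, code)
        u = aa_usage(CodonCountTable("x", counts), code)
        brute = Counter()
        for c, n in counts.items():
            brute[code.codon_to_aa[c]] += n
        total = sum(brute.values())
        for aa, f in u.freqs.items():
            assert f == pytest.approx(brute.get(aa, 0) / total)
        assert sum(u.freqs.values()) == pytest.approx(1.0)


class TestHypotheticalGc12:
    def test_all_glycine(self, code):
        assert hypothetical_gc12({"G": 1.0}, code) == pytest.approx(1.0)

    def test_all_lysine(self, code):
        assert hypothetical_gc12({"K": 1.0}, code) == pytest.approx(0.0)

    def test_linearity(self, code):
        assert hypothetical_gc12({"G": 0.5, "K": 0.5}, code) == pytest.approx(0.5)


class TestStopUsage:
    def test_simple_frequencies(self, code):
        t = CodonCountTable("x", {}, stop_counts={"TAA": 2, "TGA": 1})
        f = stop_usage([t])
        assert f == {"TAA": 2 / 3, "TAG": 0.0, "TGA": 1 / 3}

    def test_all_tag(self, code):
        f = stop_usage([CodonCountTable("x", {}, stop_counts={"TAG": 5})])
        assert f["TAG"] == 1.0

    def test_generator_weights_recovered(self, code):
        from silentbias.simulate import SimulationConfig, TaxonConfig, simulate_transcriptome
        from silentbias.codon_usage import count_codons

        weights = (0.6, 0.1, 0.3)
        tc = TaxonConfig(cell_id="c", n_transcripts=2000, stop_weights=weights,
                         length_log_mu=math.log(35), length_log_sigma=0.1)
        records, _, _ = simulate_transcriptome(SimulationConfig(seed=11, taxa=[tc]))
        t = count_codons([r.cds for r in records.values()], code)
        f = stop_usage([t])
        n = sum(t.stop_counts.values())
        for stop, w in zip(("TAA", "TAG", "TGA"), weights):
            sigma = math.sqrt(w * (1 - w) / n)
            assert abs(f[stop] - w) < 3 * sigma + 1e-12
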