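"""Codon-level statistics: counts, family frequencies, RSCU, ENc, usage nulls.

The effective number of codons (ENc) follows Wright's estimator: for each
amino acid a with n_a occurrences and synonym proportions p_i,

    F_hat_a = (n_a * sum_i p_i^2 - 1) / (n_a - 1),

class means F2/F3/F4/F6 are taken over families with 2, 3, 4 and 6
synonyms (Leu/Ser/Arg treated jointly as sixfold), and

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

capped at 61. The composition-only null expectation as a function of
silent-site GC content s is

    ENc*(s) = 2 + s + 29 / (s^2 + (1-s)^2),

which is 31 at s=0, 60.5 at s=0.5 and 32 at s=1.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .composition import GC, _codons
from .genetic_code import FYMINK, GARP, SIXFOLD_AA, GeneticCode

#: ENc class weights: 2 onefold aa (Met, Trp), 9 twofold, 1 threefold (Ile),
#: 5 fourfold, 3 sixfold (Leu, Ser, Arg).
ENC_CLASS_WEIGHTS = {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCountTable:
    """Codon counts for one transcript or one cell (pooled transcripts).

    ``counts`` covers the 61 sense codons; ``stop_counts`` tallies terminal
    stops only. ``aa_totals`` is always consistent with ``counts`` under the
    code map.
    """

    scope: str
    counts: Dict[str, int] = field(default_factory=dict)
    stop_counts: Dict[str, int] = field(default_factory=dict)

    def aa_totals(self, code: GeneticCode) -> Dict[str, int]:
        totals: Dict[str, int] = {aa: 0 for aa in code.amino_acids}
        for codon, n in self.counts.items():
            totals[code.codon_to_aa[codon]] += n
        return totals

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        counts = Counter(self.counts)
        counts.update(other.counts)
        stops = Counter(self.stop_counts)
        stops.update(other.stop_counts)
        return CodonCountTable(scope="pooled", counts=dict(counts), stop_counts=dict(stops))


def count_codons(cds_or_list, code: GeneticCode, scope: str = "transcript") -> CodonCountTable:
    """Exact codon counts; N codons dropped, terminal stop tallied separately.

    Accepts a single CDS string or an iterable of CDS strings (pooled).
    """
    if isinstance(cds_or_list, str):
        cds_list: Sequence[str] = [cds_or_list]
    else:
        cds_list = list(cds_or_list)
    counts: Counter = Counter()
    stops: Counter = Counter()
    for cds in cds_list:
        cods = _codons(cds)
        if cods and cods[-1] in code.stop_set:
            stops[cods[-1]] += 1
            cods = cods[:-1]
        for c in cods:
            if c in code.codon_to_aa and c not in code.stop_set:
                counts[c] += 1
    return CodonCountTable(scope=scope, counts=dict(counts), stop_counts=dict(stops))


def family_frequencies(table: CodonCountTable, code: GeneticCode) -> Dict[str, float]:
    """Per-codon frequency within its amino-acid family.

    The count of a codon divided by the total count of its amino acid;
    families with zero total give NaN for all their codons.
    """
    totals = table.aa_totals(code)
    freqs: Dict[str, float] = {}
    for codon in code.sense_codons:
        n_a = totals[code.codon_to_aa[codon]]
        freqs[codon] = table.counts.get(codon, 0) / n_a if n_a else math.nan
    return freqs


def rscu(table: CodonCountTable, code: GeneticCode) -> Dict[str, float]:
    """Relative synonymous codon usage: k * n_i / n_a for family size k."""
    totals = table.aa_totals(code)
    out: Dict[str, float] = {}
    for codon in code.sense_codons:
        aa = code.codon_to_aa[codon]
        n_a = totals[aa]
        k = code.family_size(aa)
        out[codon] = k * table.counts.get(codon, 0) / n_a if n_a else math.nan
    return out


@dataclass
class EncValue:
    """Wright's ENc with its per-class mean homozygosities."""

    enc: float
    class_means: Dict[int, float]
    n_families_used: int
    reason: Optional[str] = None


def _enc_family_classes(code: GeneticCode) -> Dict[str, int]:
    """Amino acid -> ENc degeneracy class (6 for Leu/Ser/Arg)."""
    classes = {}
    for aa in code.amino_acids:
        classes[aa] = 6 if aa in SIXFOLD_AA else code.family_size(aa)
    return classes


def enc_observed(table: CodonCountTable, code: GeneticCode) -> EncValue:
    """Wright's observed ENc for a count table.

    Families with n_a < 2 are excluded from their class mean. A missing
    threefold class (Ile) is replaced by (F2 + F4)/2, Wright's own
    fallback; a missing twofold or fourfold class makes ENc NaN.
    """
    totals = table.aa_totals(code)
    classes = _enc_family_classes(code)
    per_class: Dict[int, list] = {2: [], 3: [], 4: [], 6: []}
    n_used = 0
    for aa, cls in classes.items():
        if cls == 1:
            continue
        n_a = totals[aa]
        if n_a < 2:
            continue
        p_sq = sum(
            (table.counts.get(c, 0) / n_a) ** 2 for c in code.synonyms(aa)
        )
        f_hat = (n_a * p_sq - 1) / (n_a - 1)
        per_class[cls].append(f_hat)
        n_used += 1

    means: Dict[int, float] = {
        cls: (float(np.mean(vals)) if vals else math.nan)
        for cls, vals in per_class.items()
    }
    if math.isnan(means[2]) or math.isnan(means[4]):
        return EncValue(math.nan, means, n_used, reason="no estimable twofold or fourfold family")
    if math.isnan(means[3]):
        means[3] = (means[2] + means[4]) / 2.0
    if means[2] <= 0 or means[3] <= 0 or means[4] <= 0 or (per_class[6] and means[6] <= 0):
        return EncValue(math.nan, means, n_used, reason="non-positive class homozygosity")
    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4]
    if per_class[6]:
        enc += 3.0 / means[6]
    else:
        return EncValue(math.nan, means, n_used, reason="no estimable sixfold family")
    return EncValue(min(enc, 61.0), means, n_used)


def enc_expected(s: float) -> float:
    """Composition-only expected ENc at silent-site GC content ``s``."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("GC3S fraction must lie in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def expected_codon_usage_from_nt(
    aa: str, nt_freqs: Mapping[str, float], code: GeneticCode
) -> Dict[str, float]:
    """Expected synonym frequencies of ``aa`` given third-position nt usage.

    Each synonym is weighted by the frequency of its third-position
    nucleotide restricted to the family's allowed set, renormalised to sum
    to 1 over the family. For the split sixfold families the allowed set is
    taken per codon box (the synonymous set at position 3 of each codon).
    """
    synonyms = code.synonyms(aa)
    if not synonyms:
        raise KeyError(f"unknown amino acid {aa!r}")
    weights = {}
    for codon in synonyms:
        allowed = code.syn_nt_sets[(codon, 3)]
        denom = sum(nt_freqs.get(nt, 0.0) for nt in allowed)
        weights[codon] = nt_freqs.get(codon[2], 0.0) / denom if denom > 0 else math.nan
    # Box-wise weights within a split family are scaled by box size so the
    # family total is 1 (each box's restricted weights already sum to 1).
    total = sum(w for w in weights.values() if not math.isnan(w))
    if total <= 0 or any(math.isnan(w) for w in weights.values()):
        return {c: math.nan for c in synonyms}
    return {c: w / total for c, w in weights.items()}


@dataclass
class AminoAcidUsage:
    freqs: Dict[str, float]
    fymink_frac: float
    garp_frac: float
    n_residues: int


def aa_usage(table: CodonCountTable, code: GeneticCode) -> AminoAcidUsage:
    """Amino-acid frequencies plus FYMINK and GARP fractions."""
    totals = table.aa_totals(code)
    n = sum(totals.values())
    if n == 0:
        nanned = {aa: math.nan for aa in code.amino_acids}
        return AminoAcidUsage(nanned, math.nan, math.nan, 0)
    freqs = {aa: totals[aa] / n for aa in code.amino_acids}
    return AminoAcidUsage(
        freqs=freqs,
        fymink_frac=sum(freqs[a] for a in FYMINK),
        garp_frac=sum(freqs[a] for a in GARP),
        n_residues=n,
    )


def hypothetical_gc12(aa_freqs: Mapping[str, float], code: GeneticCode) -> float:
    """GC12 expected from amino-acid frequencies under equal codon usage.

    For each amino acid, the mean G/C count at positions 1-2 over its
    synonyms (divided by 2), weighted by the amino-acid frequency. This is
    the no-codon-bias GC12 given the true amino-acid composition.
    """
    total = 0.0
    for aa, f in aa_freqs.items():
        synonyms = code.synonyms(aa)
        if not synonyms:
            continue
        mean_gc = np.mean(
            [sum(nt in GC for nt in c[:2]) for c in synonyms]
        )
        total += f * mean_gc / 2.0
    return float(total)


def stop_usage(tables: Iterable[CodonCountTable]) -> Dict[str, float]:
    """Frequencies of TAA/TAG/TGA among observed terminal stops."""
    stops: Counter = Counter()
    for t in tables:
        stops.update(t.stop_counts)
    n = sum(stops.values())
    if n == 0:
        return {s: math.nan for s in ("TAA", "TAG", "TGA")}
    return {s: stops.get(s, 0) / n for s in ("TAA", "TAG", "TGA")}


def round_half_even_pct(fraction: float, ndigits: int = 2) -> float:
    """Percentage with banker's rounding, the convention for reported tables."""
    if math.isnan(fraction):
        return math.nan
    return float(round(fraction * 100.0, ndigits))
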