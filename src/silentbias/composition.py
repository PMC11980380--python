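"""Nucleotide-level composition metrics on CDS and UTR sequences.

GC4 is the G+C fraction at third positions of codons whose third position is
fourfold degenerate; GC3S uses third positions of all sense codons except
ATG and TGG; GC12 covers codon positions 1-2 (largely non-synonymous).
Strand-asymmetry skews are (A-T)/(A+T) and (G-C)/(G+C). All denominators
exclude N sites; a metric whose defining site set is empty is NaN.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genetic_code import GeneticCode

GC = frozenset("GC")


def _codons(cds: str) -> List[str]:
    cds = cds.upper()
    return [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def sense_codons_of(cds: str, code: GeneticCode) -> List[str]:
    """In-frame codons of a CDS, minus a terminal stop and any N codon."""
    cods = _codons(cds)
    if cods and cods[-1] in code.stop_set:
        cods = cods[:-1]
    return [c for c in cods if c in code.codon_to_aa and c not in code.stop_set]


def gc4(cds: str, code: GeneticCode) -> float:
    """GC fraction at fourfold-degenerate third positions; NaN if none."""
    thirds = [c[2] for c in sense_codons_of(cds, code) if c in code.fourfold_third_set]
    if not thirds:
        return math.nan
    return sum(nt in GC for nt in thirds) / len(thirds)


def gc3s(cds: str, code: GeneticCode) -> float:
    """GC fraction at third positions of all sense codons but ATG/TGG."""
    thirds = [c[2] for c in sense_codons_of(cds, code) if c in code.gc3s_eligible_set]
    if not thirds:
        return math.nan
    return sum(nt in GC for nt in thirds) / len(thirds)


def gc12(cds: str, code: GeneticCode) -> float:
    """GC fraction over positions 1 and 2 of all sense codons."""
    cods = sense_codons_of(cds, code)
    if not cods:
        raise ValueError("gc12 undefined for a CDS with no sense codons")
    sites = [nt for c in cods for nt in c[:2]]
    return sum(nt in GC for nt in sites) / len(sites)


def skews(sites: Iterable[str]) -> Tuple[float, float]:
    """AT skew (A-T)/(A+T) and GC skew (G-C)/(G+C) over a site multiset.

    Either skew is NaN when its denominator is zero.
    """
    counts = Counter(nt.upper() for nt in sites)
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    at = (a - t) / (a + t) if a + t else math.nan
    gcs = (g - c) / (g + c) if g + c else math.nan
    return at, gcs


def silent_third_sites(cds: str, code: GeneticCode) -> List[str]:
    """Third-position nucleotides at synonymously variable (degeneracy>1) codons."""
    return [
        c[2]
        for c in sense_codons_of(cds, code)
        if code.third_pos_degeneracy[c] > 1
    ]


def gc_fraction(seq: str) -> float:
    """Plain GC fraction of a sequence, ignoring N; NaN if empty."""
    seq = seq.upper()
    acgt = [nt for nt in seq if nt in "ACGT"]
    if not acgt:
        return math.nan
    return sum(nt in GC for nt in acgt) / len(acgt)


def positional_gc3s_profile(
    cds_list: Sequence[str], code: GeneticCode, window: int = 50
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean silent-site GC by codon index from the 5' and 3' CDS ends.

    Returns ``(mean_5p, n_5p, mean_3p, n_3p)``, each of length ``window``;
    index 0 is the codon adjacent to the CDS-UTR boundary. Transcripts
    shorter than the window contribute only their available indices. Codons
    ineligible for GC3S (ATG, TGG, N codons) are skipped at their index.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sums5 = np.zeros(window)
    n5 = np.zeros(window)
    sums3 = np.zeros(window)
    n3 = np.zeros(window)
    for cds in cds_list:
        cods = sense_codons_of(cds, code)
        for i, c in enumerate(cods[:window]):
            if c in code.gc3s_eligible_set:
                sums5[i] += c[2] in GC
                n5[i] += 1
        for i, c in enumerate(reversed(cods[-window:] if len(cods) >= window else cods)):
            if c in code.gc3s_eligible_set:
                sums3[i] += c[2] in GC
                n3[i] += 1
    with np.errstate(invalid="ignore"):
        return sums5 / np.where(n5 > 0, n5, np.nan), n5, sums3 / np.where(n3 > 0, n3, np.nan), n3


#: Bias categories follow the taxon classification by median GC4:
#: extreme AT bias below 15%, intermediate to 40%, non-biased to 60%,
#: GC-biased above.
def classify_bias(median_gc4: float) -> str:
    if median_gc4 is None or (isinstance(median_gc4, float) and math.isnan(median_gc4)):
        return "unclassified"
    if not 0.0 <= median_gc4 <= 1.0:
        raise ValueError("median GC4 must be a fraction in [0, 1]")
    if median_gc4 < 0.15:
        return "AT-biased"
    if median_gc4 < 0.40:
        return "intermediate"
    if median_gc4 <= 0.60:
        return "non-biased"
    return "GC-biased"


@dataclass
class DinucleotideBias:
    """Observed/expected ratio per dinucleotide under a single-nucleotide null."""

    ratios: dict
    n_dinucleotides: int


def utr_dinucleotide_bias(utrs: Sequence[str]) -> DinucleotideBias:
    """Per-dinucleotide obs/exp ratio f(XY) / (f(X) f(Y)) over UTRs.

    Overlapping windows within each UTR; pairs never span two UTRs. The
    expectation uses single-nucleotide frequencies pooled over the same
    UTRs, so i.i.d. sequence gives ratios near 1. Ratio is NaN when the
    expected frequency is zero.
    """
    din = Counter()
    mono = Counter()
    for utr in utrs:
        s = utr.upper()
        mono.update(nt for nt in s if nt in "ACGT")
        for i in range(len(s) - 1):
            pair = s[i : i + 2]
            if pair[0] in "ACGT" and pair[1] in "ACGT":
                din[pair] += 1
    n_d = sum(din.values())
    n_m = sum(mono.values())
    ratios = {}
    for x in "ACGT":
        for y in "ACGT":
            pair = x + y
            if n_d == 0 or n_m == 0:
                ratios[pair] = math.nan
                continue
            exp = (mono[x] / n_m) * (mono[y] / n_m)
            obs = din[pair] / n_d
            ratios[pair] = obs / exp if exp > 0 else math.nan
    return DinucleotideBias(ratios=ratios, n_dinucleotides=n_d)


@dataclass
class CompositionSummary:
    """Per-transcript composition metrics (fractions; NaN where undefined)."""

    gc4: float
    gc3s: float
    gc12: float
    at_skew_silent: float
    gc_skew_silent: float
    n_fourfold_sites: int
    n_gc3s_sites: int
    n_codons: int
    utr5_gc: float = math.nan
    utr3_gc: float = math.nan


def summarize_cds(
    cds: str,
    code: GeneticCode,
    utr5: Optional[str] = None,
    utr3: Optional[str] = None,
) -> CompositionSummary:
    """Compute the full composition summary for one transcript."""
    cods = sense_codons_of(cds, code)
    silent = silent_third_sites(cds, code)
    at_sk, gc_sk = skews(silent) if silent else (math.nan, math.nan)
    return CompositionSummary(
        gc4=gc4(cds, code),
        gc3s=gc3s(cds, code),
        gc12=gc12(cds, code) if cods else math.nan,
        at_skew_silent=at_sk,
        gc_skew_silent=gc_sk,
        n_fourfold_sites=sum(c in code.fourfold_third_set for c in cods),
        n_gc3s_sites=sum(c in code.gc3s_eligible_set for c in cods),
        n_codons=len(cods),
        utr5_gc=gc_fraction(utr5) if utr5 else math.nan,
        utr3_gc=gc_fraction(utr3) if utr3 else math.nan,
    )
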