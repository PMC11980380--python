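"""Site-specific synonymous dinucleotide usage (SSDU).

SSDU measures dinucleotide over/under-use at the three codon frame
positions (pos1 = codon positions 1-2, pos2 = positions 2-3, bridge =
position 3 joined to the next codon's position 1) relative to a null that
conditions on the amino-acid sequence and on single-nucleotide frequencies
stratified by codon position and degeneracy class (onefold..fourfold
sites).

For each dinucleotide h and frame position p, synonymous groups g are amino
acids (pos1/pos2) or ordered amino-acid pairs (bridge). With o_g the
observed proportion of g's occurrences hosting h at p, e_g the null
probability of hosting h, and n_g the occurrence count,

    SSDU_{h,p} = sum_g n_g (o_g / e_g) / sum_g n_g,

over informative groups (0 < e_g < 1, n_g above a minimum). SSDU is 1
under the null in expectation; values above 1 mark over-use.

The null codon distribution for amino acid a assigns each synonym a weight
equal to the product over its three positions of the stratum frequency of
its own nucleotide (stratum = (position, degeneracy class of the codon at
that position)), renormalised over a's synonyms. With uniform stratum
frequencies every synonym gets weight (1/4)^3, so the null reduces exactly
to the equal-usage synonymous dinucleotide usage (SDU) statistic this
metric generalises.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .composition import _codons
from .genetic_code import NUCLEOTIDES, GeneticCode, position_degeneracy

FRAME_POSITIONS = ("pos1", "pos2", "bridge")
DINUCLEOTIDES = tuple(x + y for x in NUCLEOTIDES for y in NUCLEOTIDES)


@dataclass
class PositionClassFreqs:
    """Nucleotide frequencies per (codon position, degeneracy class) stratum.

    ``freqs[(pos, cls)]`` is a dict over A/C/G/T summing to 1;
    ``site_counts`` holds the number of sites behind each stratum; strata
    with zero sites are absent from ``freqs``.
    """

    freqs: Dict[Tuple[int, int], Dict[str, float]]
    site_counts: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def get(self, pos: int, cls: int) -> Optional[Dict[str, float]]:
        return self.freqs.get((pos, cls))


def uniform_position_class_freqs() -> PositionClassFreqs:
    """All strata uniform over A/C/G/T (the equal-usage SDU null)."""
    freqs = {
        (pos, cls): {nt: 0.25 for nt in NUCLEOTIDES}
        for pos in (1, 2, 3)
        for cls in (1, 2, 3, 4)
    }
    return PositionClassFreqs(freqs=freqs)


def codon_sequences(cds_list: Iterable[str], code: GeneticCode) -> List[List[str]]:
    """Sense-codon runs per transcript, breaking chains at N codons.

    The terminal stop is dropped, so bridges never reach into a stop. A
    codon containing N ends the current run; bridge pairs are only counted
    within a run.
    """
    runs: List[List[str]] = []
    for cds in cds_list:
        cods = _codons(cds)
        if cods and cods[-1] in code.stop_set:
            cods = cods[:-1]
        current: List[str] = []
        for c in cods:
            if c in code.codon_to_aa and c not in code.stop_set:
                current.append(c)
            else:
                if current:
                    runs.append(current)
                current = []
        if current:
            runs.append(current)
    return runs


def estimate_position_class_freqs(
    cds_list: Iterable[str], code: GeneticCode
) -> PositionClassFreqs:
    """Empirical stratum frequencies pooled over a cell's transcripts."""
    counts: Dict[Tuple[int, int], Counter] = {}
    for run in codon_sequences(cds_list, code):
        for codon in run:
            for pos in (1, 2, 3):
                cls = position_degeneracy(code, codon, pos)
                counts.setdefault((pos, cls), Counter())[codon[pos - 1]] += 1
    freqs = {}
    site_counts = {}
    for stratum, ctr in counts.items():
        n = sum(ctr.values())
        site_counts[stratum] = n
        freqs[stratum] = {nt: ctr.get(nt, 0) / n for nt in NUCLEOTIDES}
    return PositionClassFreqs(freqs=freqs, site_counts=site_counts)


def null_codon_probability(
    codon: str, aa: str, freqs: PositionClassFreqs, code: GeneticCode
) -> float:
    """Null probability of ``codon`` among the synonyms of ``aa``."""
    dist = null_family_distribution(aa, freqs, code)
    if codon not in dist:
        raise ValueError(f"{codon} does not encode {aa}")
    return dist[codon]


def _codon_weight(codon: str, freqs: PositionClassFreqs, code: GeneticCode) -> float:
    w = 1.0
    for pos in (1, 2, 3):
        cls = position_degeneracy(code, codon, pos)
        stratum = freqs.get(pos, cls)
        if stratum is None:
            # Empty stratum in the data: fall back to a uniform factor, which
            # cancels in the renormalisation unless synonyms differ here.
            factor = 0.25
        else:
            factor = stratum[codon[pos - 1]]
        w *= factor
    return w


def null_family_distribution(
    aa: str, freqs: PositionClassFreqs, code: GeneticCode
) -> Dict[str, float]:
    """Null distribution over the synonyms of ``aa`` (sums to 1)."""
    synonyms = code.synonyms(aa)
    weights = {c: _codon_weight(c, freqs, code) for c in synonyms}
    total = sum(weights.values())
    if total <= 0:
        return {c: 1.0 / len(synonyms) for c in synonyms}
    return {c: w / total for c, w in weights.items()}


@dataclass
class SSDUCell:
    """One (dinucleotide, frame position) entry of an SSDU table."""

    dinucleotide: str
    frame_position: str
    observed: float
    expected: float
    ssdu: float
    n_groups: int
    n_occurrences: int


@dataclass
class SSDUTable:
    cells: Dict[Tuple[str, str], SSDUCell]

    def ratio(self, dinucleotide: str, frame_position: str) -> float:
        cell = self.cells.get((dinucleotide, frame_position))
        return cell.ssdu if cell else math.nan

    def mean_ratio(self) -> float:
        vals = [c.ssdu for c in self.cells.values() if not math.isnan(c.ssdu)]
        return float(np.mean(vals)) if vals else math.nan

    def log2_ratio(self, dinucleotide: str, frame_position: str) -> float:
        r = self.ratio(dinucleotide, frame_position)
        return math.log2(r) if r and r > 0 else math.nan


def _count_observed(
    runs: Sequence[Sequence[str]], code: GeneticCode
) -> Tuple[Counter, Counter]:
    """Codon counts and adjacent ordered codon-pair counts."""
    codon_counts: Counter = Counter()
    pair_counts: Counter = Counter()
    for run in runs:
        codon_counts.update(run)
        for i in range(len(run) - 1):
            pair_counts[(run[i], run[i + 1])] += 1
    return codon_counts, pair_counts


def compute_ssdu(
    cds_list: Iterable[str],
    freqs: PositionClassFreqs,
    code: GeneticCode,
    min_group_count: int = 10,
) -> SSDUTable:
    """SSDU over all 16 dinucleotides x 3 frame positions for one cell.

    ``freqs`` is usually :func:`estimate_position_class_freqs` on the same
    records; pass a known table to evaluate against an external null.
    Groups with e in {0, 1} carry no synonymous information and are
    excluded, as are groups with fewer than ``min_group_count``
    occurrences.
    """
    runs = codon_sequences(cds_list, code)
    codon_counts, pair_counts = _count_observed(runs, code)

    null_dists = {
        aa: null_family_distribution(aa, freqs, code) for aa in code.amino_acids
    }
    # Null marginals of position-3 and position-1 nucleotides per amino acid
    # (for the bridge, which assumes adjacent codons independent under the
    # single-nucleotide null).
    marg3 = {
        aa: {
            nt: sum(p for c, p in dist.items() if c[2] == nt) for nt in NUCLEOTIDES
        }
        for aa, dist in null_dists.items()
    }
    marg1 = {
        aa: {
            nt: sum(p for c, p in dist.items() if c[0] == nt) for nt in NUCLEOTIDES
        }
        for aa, dist in null_dists.items()
    }

    # Observed per-amino-acid totals and per-pair totals.
    aa_counts: Counter = Counter()
    for codon, n in codon_counts.items():
        aa_counts[code.codon_to_aa[codon]] += n
    aa_pair_counts: Counter = Counter()
    bridge_host_counts: Counter = Counter()
    for (c1, c2), n in pair_counts.items():
        key = (code.codon_to_aa[c1], code.codon_to_aa[c2])
        aa_pair_counts[key] += n
        bridge_host_counts[key + (c1[2], c2[0])] += n

    cells: Dict[Tuple[str, str], SSDUCell] = {}
    for h in DINUCLEOTIDES:
        for fp in FRAME_POSITIONS:
            num = 0.0
            den = 0
            obs_sum = 0.0
            exp_sum = 0.0
            n_groups = 0
            if fp in ("pos1", "pos2"):
                sl = slice(0, 2) if fp == "pos1" else slice(1, 3)
                for aa, dist in null_dists.items():
                    n_g = aa_counts.get(aa, 0)
                    if n_g < min_group_count:
                        continue
                    e_g = sum(p for c, p in dist.items() if c[sl] == h)
                    if not 0.0 < e_g < 1.0:
                        continue
                    o_g = (
                        sum(
                            codon_counts.get(c, 0)
                            for c in dist
                            if c[sl] == h
                        )
                        / n_g
                    )
                    num += n_g * (o_g / e_g)
                    den += n_g
                    obs_sum += n_g * o_g
                    exp_sum += n_g * e_g
                    n_groups += 1
            else:
                for (aa1, aa2), n_g in aa_pair_counts.items():
                    if n_g < min_group_count:
                        continue
                    e_g = marg3[aa1][h[0]] * marg1[aa2][h[1]]
                    if not 0.0 < e_g < 1.0:
                        continue
                    o_g = bridge_host_counts.get((aa1, aa2, h[0], h[1]), 0) / n_g
                    num += n_g * (o_g / e_g)
                    den += n_g
                    obs_sum += n_g * o_g
                    exp_sum += n_g * e_g
                    n_groups += 1
            if den == 0:
                cells[(h, fp)] = SSDUCell(h, fp, math.nan, math.nan, math.nan, 0, 0)
            else:
                cells[(h, fp)] = SSDUCell(
                    h,
                    fp,
                    observed=obs_sum / den,
                    expected=exp_sum / den,
                    ssdu=num / den,
                    n_groups=n_groups,
                    n_occurrences=den,
                )
    return SSDUTable(cells=cells)


def simulate_from_null(
    aa_sequences: Iterable[str],
    freqs: PositionClassFreqs,
    code: GeneticCode,
    rng: np.random.Generator,
) -> List[str]:
    """Draw CDS strings codon-by-codon from the stratified null.

    Used for null-calibration checks: SSDU computed on the output with the
    same ``freqs`` averages 1.
    """
    tables = {}
    for aa in code.amino_acids:
        dist = null_family_distribution(aa, freqs, code)
        synonyms = list(dist)
        tables[aa] = (synonyms, np.cumsum([dist[c] for c in synonyms]))
    out = []
    for aa_seq in aa_sequences:
        draws = rng.random(len(aa_seq))
        codons = []
        for aa, u in zip(aa_seq, draws):
            synonyms, cum = tables[aa]
            codons.append(synonyms[min(int(np.searchsorted(cum, u)), len(synonyms) - 1)])
        out.append("".join(codons))
    return out
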