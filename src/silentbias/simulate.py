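"""Synthetic multi-taxon transcriptomes with controllable silent-site bias.

The generator emulates the statistical structure the analysis pipeline
assumes: a panel of cells spanning silent-site GC content from extreme AT
bias (~2-3% GC4) to GC-rich (~72-76%), a shared amino-acid profile across
taxa, log-normal transcript lengths and expression, optional
expression-linked selection on an optimal codon set, i.i.d. UTRs with
taxon-specific composition, elevated silent-site GC near CDS ends, and
injected cross-cell contaminants with coverage asymmetry (index-hopping
artifacts).

Codon choice follows the same stratified single-nucleotide null the SSDU
statistic tests: given the amino acid, each synonym's weight is the product
over its positions of the target nucleotide distribution, renormalised
within the family, so data generated with zero selection is exactly its
own SSDU null. Selection tilts the weight of the designated optimal codon
by exp(s_sel * log10(expression)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, build_standard_code
from .io import GeneFamilyAlignment, TranscriptRecord
from .ssdu import PositionClassFreqs, null_family_distribution

NT = ("A", "C", "G", "T")

#: Shared amino-acid profile: Leu/Lys/Ile-enriched, Met/His/Cys/Trp-poor,
#: the usage pattern conserved across deep eukaryotic lineages.
DEFAULT_AA_PROFILE: Dict[str, float] = {
    "A": 0.070, "R": 0.055, "N": 0.045, "D": 0.053, "C": 0.015,
    "Q": 0.040, "E": 0.065, "G": 0.060, "H": 0.022, "I": 0.065,
    "L": 0.105, "K": 0.070, "M": 0.020, "F": 0.040, "P": 0.048,
    "S": 0.070, "T": 0.055, "W": 0.010, "Y": 0.030, "V": 0.062,
}


def silent_nt_dist(gc: float, at_skew: float = 0.10, gc_skew: float = -0.10) -> Dict[str, float]:
    """Four-nucleotide distribution with a given GC level and mild skews.

    Defaults give positive AT skew (A over T) and negative GC skew (C over
    G), the silent-site pattern typical of these transcriptomes.
    """
    a = (1 - gc) * (1 + at_skew) / 2
    t = (1 - gc) * (1 - at_skew) / 2
    g = gc * (1 + gc_skew) / 2
    c = gc * (1 - gc_skew) / 2
    return {"A": a, "C": c, "G": g, "T": t}


@dataclass
class TaxonConfig:
    """Generation parameters for one cell."""

    cell_id: str
    target_gc4: float = 0.45
    aa_profile: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_PROFILE))
    n_transcripts: int = 300
    length_log_mu: float = math.log(250.0)  # codons
    length_log_sigma: float = 0.45
    expression_log_mu: float = math.log(50.0)  # arbitrary abundance units
    expression_log_sigma: float = 1.8
    s_sel: float = 0.0
    optimal_codon_map: Optional[Mapping[str, str]] = None
    utr5_len_log_mu: float = math.log(150.0)
    utr5_len_log_sigma: float = 0.45
    utr3_len_log_mu: float = math.log(200.0)
    utr3_len_log_sigma: float = 0.45
    utr5_nt_dist: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.33, "C": 0.24, "G": 0.16, "T": 0.27}
    )
    utr3_nt_dist: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.27, "C": 0.16, "G": 0.24, "T": 0.33}
    )
    boundary_gc_boost: Tuple[int, float] = (0, 0.0)  # (codon window, delta)
    stop_weights: Tuple[float, float, float] = (0.55, 0.10, 0.35)  # TAA, TAG, TGA
    coverage_log_mu: float = math.log(60.0)
    coverage_log_sigma: float = 0.5
    regime: str = "silent_only"  # or "all_positions"
    gc_jitter_sd: float = 0.0  # per-transcript spread of the silent GC target

    @property
    def target_silent_nt_dist(self) -> Dict[str, float]:
        return silent_nt_dist(self.target_gc4)


@dataclass
class ContaminationEvent:
    donor_cell: str
    recipient_cell: str
    n_seqs: int = 5
    coverage_ratio: float = 0.05
    mutation_rate: float = 0.003


@dataclass
class SimulationConfig:
    seed: int = 0
    taxa: List[TaxonConfig] = field(default_factory=list)
    contamination: List[ContaminationEvent] = field(default_factory=list)
    n_gene_families: Optional[int] = None  # default: one per transcript slot
    total_reads: int = 2_000_000

    def validate(self) -> None:
        if not self.taxa:
            raise ValueError("no taxa configured")
        for t in self.taxa:
            total = sum(t.aa_profile.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{t.cell_id}: aa_profile sums to {total}")
            if not 0.0 <= t.target_gc4 <= 1.0:
                raise ValueError(f"{t.cell_id}: target_gc4 out of [0,1]")
            if t.s_sel < 0:
                raise ValueError(f"{t.cell_id}: s_sel must be >= 0")
            if t.regime not in ("silent_only", "all_positions"):
                raise ValueError(f"{t.cell_id}: unknown regime {t.regime!r}")
        for ev in self.contamination:
            if ev.coverage_ratio <= 0:
                raise ValueError("contamination coverage_ratio must be > 0")
            cells = {t.cell_id for t in self.taxa}
            if ev.donor_cell not in cells or ev.recipient_cell not in cells:
                raise ValueError("contamination names an unknown cell")


def default_panel_config(seed: int = 0, n_transcripts: int = 300) -> SimulationConfig:
    """The default five-taxon panel spanning the observed GC4 range."""
    targets = [0.03, 0.10, 0.25, 0.45, 0.72]
    taxa = [
        TaxonConfig(cell_id=f"cell_gc{int(round(g * 100)):02d}", target_gc4=g,
                    n_transcripts=n_transcripts)
        for g in targets
    ]
    return SimulationConfig(seed=seed, taxa=taxa)


def stratified_freqs(dist: Mapping[str, float]) -> PositionClassFreqs:
    """A PositionClassFreqs table with every stratum equal to ``dist``.

    This is the generating null of a zero-selection taxon: pass it to
    compute_ssdu to evaluate SSDU against the true generating model.
    """
    freqs = {
        (pos, cls): {nt: float(dist[nt]) for nt in NT}
        for pos in (1, 2, 3)
        for cls in (1, 2, 3, 4)
    }
    return PositionClassFreqs(freqs=freqs)


def _boosted(dist: Mapping[str, float], delta: float) -> Dict[str, float]:
    """Mix ``delta`` of the mass toward an even G/C split."""
    return {
        "A": dist["A"] * (1 - delta),
        "T": dist["T"] * (1 - delta),
        "G": dist["G"] * (1 - delta) + delta / 2,
        "C": dist["C"] * (1 - delta) + delta / 2,
    }


class _CodonSampler:
    """Per-amino-acid cumulative tables for a fixed nucleotide target."""

    def __init__(self, dist: Mapping[str, float], code: GeneticCode):
        self.code = code
        freqs = stratified_freqs(dist)
        self.dists = {
            aa: null_family_distribution(aa, freqs, code)
            for aa in code.amino_acids
        }
        self._tables = {
            aa: (list(d), np.cumsum(list(d.values())))
            for aa, d in self.dists.items()
        }

    def tilted_tables(
        self, s_sel: float, log_expr: float, optimal: Mapping[str, str]
    ) -> Dict[str, Tuple[List[str], np.ndarray]]:
        if s_sel == 0.0:
            return self._tables
        tables = {}
        for aa, dist in self.dists.items():
            best = optimal.get(aa)
            w = np.array(
                [
                    p * math.exp(s_sel * log_expr) if c == best else p
                    for c, p in dist.items()
                ]
            )
            w /= w.sum()
            tables[aa] = (list(dist), np.cumsum(w))
        return tables

    def draw(self, aa: str, u: float, tables=None) -> str:
        synonyms, cum = (tables or self._tables)[aa]
        return synonyms[min(int(np.searchsorted(cum, u)), len(synonyms) - 1)]


def most_at_rich_synonym(aa: str, code: GeneticCode) -> str:
    """Default optimal codon: the synonym with the most A/T, ties by A count
    then lexicographic order."""
    return max(
        code.synonyms(aa),
        key=lambda c: (sum(nt in "AT" for nt in c), c.count("A"), [-ord(x) for x in c]),
    )


def _draw_iid(dist: Mapping[str, float], n: int, rng: np.random.Generator) -> str:
    nts = list(dist)
    p = np.array([dist[k] for k in nts], dtype=float)
    p /= p.sum()
    return "".join(np.array(nts)[rng.choice(len(nts), size=n, p=p)])


def _random_cds_all_positions(
    n_codons: int, gc: float, code: GeneticCode, rng: np.random.Generator
) -> str:
    """Random stop-free codons with the same GC target at every position."""
    dist = silent_nt_dist(gc)
    nts = list(dist)
    p = np.array([dist[k] for k in nts])
    p /= p.sum()
    codons = ["ATG"]
    while len(codons) < n_codons:
        need = n_codons - len(codons)
        draw = rng.choice(len(nts), size=(need + 8, 3), p=p)
        for row in draw:
            codon = "".join(nts[i] for i in row)
            if codon not in code.stop_set and len(codons) < n_codons:
                codons.append(codon)
    return "".join(codons)


def simulate_transcriptome(
    config: SimulationConfig,
) -> Tuple[
    Dict[str, TranscriptRecord],
    Dict[str, GeneFamilyAlignment],
    pd.DataFrame,
]:
    """Generate records, trivial per-family alignments, and the truth table.

    Gene families are shared across taxa: each family fixes one protein
    (drawn once from the shared profile) that every owning cell encodes
    with its own codon choices, so family alignments are gap-free and the
    cross-taxon amino-acid profile is conserved by construction. Read
    counts are multinomial per cell with rates proportional to expression
    times transcript length.
    """
    config.validate()
    code = build_standard_code()
    rng = np.random.default_rng(config.seed)

    n_families = config.n_gene_families or max(t.n_transcripts for t in config.taxa)

    # Family scaffolds: length (codons) and amino-acid sequence.
    base_profile = dict(config.taxa[0].aa_profile)
    aa_letters = sorted(base_profile)
    aa_p = np.array([base_profile[a] for a in aa_letters])
    aa_p /= aa_p.sum()
    fam_meta: List[Tuple[str, int, str]] = []
    ref_length = config.taxa[0]
    for f in range(n_families):
        n_codons = max(
            30,
            int(round(rng.lognormal(ref_length.length_log_mu, ref_length.length_log_sigma))),
        )
        aa_seq = "M" + "".join(
            np.array(aa_letters)[rng.choice(len(aa_letters), size=n_codons - 1, p=aa_p)]
        )
        fam_meta.append((f"fam{f:05d}", n_codons, aa_seq))

    records: Dict[str, TranscriptRecord] = {}
    truth_rows: List[dict] = []
    fam_rows: Dict[str, Dict[str, str]] = {f[0]: {} for f in fam_meta}

    for taxon in config.taxa:
        own_profile = taxon.aa_profile != base_profile
        sampler = _CodonSampler(taxon.target_silent_nt_dist, code)
        window, delta = taxon.boundary_gc_boost
        boosted_sampler = (
            _CodonSampler(_boosted(taxon.target_silent_nt_dist, delta), code)
            if window > 0 and delta > 0
            else None
        )
        optimal = dict(taxon.optimal_codon_map or {})
        if taxon.s_sel > 0 and not optimal:
            optimal = {aa: most_at_rich_synonym(aa, code) for aa in code.amino_acids}

        expressions = rng.lognormal(
            taxon.expression_log_mu, taxon.expression_log_sigma, taxon.n_transcripts
        )
        coverages = rng.lognormal(
            taxon.coverage_log_mu, taxon.coverage_log_sigma, taxon.n_transcripts
        )
        stops = np.array(["TAA", "TAG", "TGA"])
        stop_p = np.array(taxon.stop_weights, dtype=float)
        stop_p /= stop_p.sum()

        for i in range(taxon.n_transcripts):
            fam_id, n_codons, aa_seq = fam_meta[i % n_families]
            tid = f"{taxon.cell_id}_t{i:05d}"
            expr = float(expressions[i])

            if taxon.regime == "all_positions":
                gc_t = float(np.clip(rng.uniform(0.25, 0.75), 0.01, 0.99))
                cds_body = _random_cds_all_positions(n_codons, gc_t, code, rng)
            else:
                if own_profile:
                    letters = sorted(taxon.aa_profile)
                    p = np.array([taxon.aa_profile[a] for a in letters], dtype=float)
                    p /= p.sum()
                    aa_seq_t = "M" + "".join(
                        np.array(letters)[rng.choice(len(letters), size=n_codons - 1, p=p)]
                    )
                else:
                    aa_seq_t = aa_seq
                if taxon.gc_jitter_sd > 0:
                    gc_t = float(
                        np.clip(
                            rng.normal(taxon.target_gc4, taxon.gc_jitter_sd), 0.01, 0.99
                        )
                    )
                    sampler_t = _CodonSampler(silent_nt_dist(gc_t), code)
                else:
                    sampler_t = sampler
                tables = sampler_t.tilted_tables(
                    taxon.s_sel, math.log10(max(expr, 1e-12)), optimal
                )
                if boosted_sampler is not None:
                    btables = boosted_sampler.tilted_tables(
                        taxon.s_sel, math.log10(max(expr, 1e-12)), optimal
                    )
                draws = rng.random(len(aa_seq_t))
                codons = []
                for j, aa in enumerate(aa_seq_t):
                    boundary = (
                        boosted_sampler is not None
                        and (j < window or j >= len(aa_seq_t) - window)
                    )
                    codons.append(
                        sampler.draw(aa, draws[j], btables if boundary else tables)
                    )
                cds_body = "".join(codons)

            stop = str(stops[rng.choice(3, p=stop_p)])
            utr5 = _draw_iid(
                taxon.utr5_nt_dist,
                int(round(rng.lognormal(taxon.utr5_len_log_mu, taxon.utr5_len_log_sigma))),
                rng,
            )
            utr3 = _draw_iid(
                taxon.utr3_nt_dist,
                int(round(rng.lognormal(taxon.utr3_len_log_mu, taxon.utr3_len_log_sigma))),
                rng,
            )
            cds = cds_body + stop
            records[tid] = rec = TranscriptRecord(
                transcript_id=tid,
                cell_id=taxon.cell_id,
                gene_family_id=fam_id,
                cds=cds,
                utr5=utr5 or None,
                utr3=utr3 or None,
                kmer_coverage=float(coverages[i]),
            )
            rec._expression = expr
            fam_rows[fam_id][tid] = cds
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "cell_id": taxon.cell_id,
                    "gene_family_id": fam_id,
                    "true_expression": expr,
                    "target_gc4": taxon.target_gc4,
                    "s_sel": taxon.s_sel,
                    "regime": taxon.regime,
                    "contaminant": False,
                }
            )

    truth = pd.DataFrame(truth_rows)
    if config.contamination:
        records, truth = inject_contamination(records, truth, config, rng, code)
        for tid, rec in records.items():
            if tid not in fam_rows.get(rec.gene_family_id, {}):
                fam_rows.setdefault(rec.gene_family_id, {})[tid] = rec.cds

    _assign_read_counts(records, config.total_reads, rng)
    truth = truth.merge(
        pd.DataFrame(
            {
                "transcript_id": list(records),
                "read_count": [records[t].read_count for t in records],
                "kmer_coverage": [records[t].kmer_coverage for t in records],
            }
        ),
        on="transcript_id",
    )

    alignments = {
        fam: GeneFamilyAlignment(fam, _pad_rows(rows))
        for fam, rows in fam_rows.items()
        if rows
    }
    return records, alignments, truth


def _pad_rows(rows: Dict[str, str]) -> Dict[str, str]:
    """Pad shorter sequences with trailing gaps (family proteins share a
    scaffold, so members only differ in length when truncated)."""
    width = max(len(s) for s in rows.values())
    return {t: s + "-" * (width - len(s)) for t, s in rows.items()}


def _assign_read_counts(
    records: Dict[str, TranscriptRecord],
    total_reads: int,
    rng: np.random.Generator,
) -> None:
    by_cell: Dict[str, List[str]] = {}
    for tid, rec in records.items():
        by_cell.setdefault(rec.cell_id, []).append(tid)
    for cell in sorted(by_cell):
        tids = sorted(by_cell[cell])
        rates = np.array(
            [records[t]._expression * len(records[t].cds) for t in tids]
        )
        p = rates / rates.sum()
        counts = rng.multinomial(total_reads, p)
        for t, c in zip(tids, counts):
            records[t].read_count = float(c)


def inject_contamination(
    records: Dict[str, TranscriptRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    code: Optional[GeneticCode] = None,
) -> Tuple[Dict[str, TranscriptRecord], pd.DataFrame]:
    """Copy donor sequences into recipient cells as index-hopping artifacts.

    Each contaminant is a near-identical (>=99%) copy of a donor transcript
    whose family the recipient also owns with healthy coverage, carrying
    coverage scaled by ``coverage_ratio``.
    """
    code = code or build_standard_code()
    new_rows = []
    for ev in config.contamination:
        if ev.coverage_ratio <= 0:
            raise ValueError("coverage_ratio must be > 0")
        donor_tids = sorted(
            t for t, r in records.items() if r.cell_id == ev.donor_cell
        )
        recipient_by_fam = {
            r.gene_family_id: r
            for t, r in records.items()
            if r.cell_id == ev.recipient_cell
        }
        eligible = [
            t
            for t in donor_tids
            if recipient_by_fam.get(records[t].gene_family_id) is not None
            and recipient_by_fam[records[t].gene_family_id].kmer_coverage > 20
        ]
        chosen = list(rng.choice(eligible, size=min(ev.n_seqs, len(eligible)), replace=False))
        for k, donor_tid in enumerate(sorted(chosen)):
            donor = records[donor_tid]
            seq = _mutate(donor.cds, ev.mutation_rate, rng, code)
            tid = f"{ev.recipient_cell}_contam{k:03d}"
            expr = getattr(donor, "_expression", 1.0) * ev.coverage_ratio
            rec = TranscriptRecord(
                transcript_id=tid,
                cell_id=ev.recipient_cell,
                gene_family_id=donor.gene_family_id,
                cds=seq,
                kmer_coverage=donor.kmer_coverage * ev.coverage_ratio,
            )
            rec._expression = expr
            records[tid] = rec
            new_rows.append(
                {
                    "transcript_id": tid,
                    "cell_id": ev.recipient_cell,
                    "gene_family_id": donor.gene_family_id,
                    "true_expression": expr,
                    "target_gc4": math.nan,
                    "s_sel": math.nan,
                    "regime": "contaminant",
                    "contaminant": True,
                    "donor_transcript_id": donor_tid,
                }
            )
    if new_rows:
        truth = pd.concat([truth, pd.DataFrame(new_rows)], ignore_index=True)
    return records, truth


def _mutate(
    cds: str, rate: float, rng: np.random.Generator, code: GeneticCode
) -> str:
    """Substitute ~rate of third positions without creating internal stops."""
    seq = list(cds)
    n_codons = len(cds) // 3
    n_mut = max(1, int(round(rate * len(cds))))
    # Mutate third positions of internal codons only; identity stays >= 99%.
    candidates = rng.permutation(max(n_codons - 2, 1))[:n_mut]
    for ci in candidates:
        pos = ci * 3 + 2
        for nt in "CAGT":
            if nt != seq[pos]:
                codon = "".join(seq[ci * 3 : ci * 3 + 2]) + nt
                if codon not in code.stop_set:
                    seq[pos] = nt
                    break
    return "".join(seq)


# ---------------------------------------------------------------------------
# Deterministic curation demonstration fixture
# ---------------------------------------------------------------------------

_STOPS = frozenset(("TAA", "TAG", "TGA"))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA, n_codons codons total.

    Aperiodic on purpose: repeated-cassette sequences share long shifted
    exact substrings, which would trip the 50-bp duplicate rule.
    """
    code = build_standard_code()
    sense = [c for c in code.sense_codons]
    body = [sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _mutate_at(seq: str, positions: Sequence[int]) -> str:
    """Deterministic substitutions that never create a stop codon."""
    s = list(seq)
    for pos in positions:
        ci = pos // 3
        for nt in "CGAT":
            if nt != s[pos]:
                codon = "".join(s[ci * 3 : ci * 3 + 3])
                codon = codon[: pos % 3] + nt + codon[pos % 3 + 1 :]
                if codon not in _STOPS:
                    s[pos] = nt
                    break
    return "".join(s)


def curation_fixture() -> Tuple[Dict[str, TranscriptRecord], Dict[str, GeneFamilyAlignment]]:
    """A 14-sequence, 3-cell, 2-family dataset with one planted violation
    per curation rule.

    Planted artifacts: B1 is a cross-cell near-copy (99.7% identical to A1)
    with contaminant-like coverage asymmetry; B3 is a 99.3% cross-cell copy
    that sits just inside the keep side of the coverage gates; A2 is a 96%
    same-cell duplicate; A3 shares a 60-bp exact run with A1; A4 is a short
    fragment; A5 a short same-cell paralog; D1 a 35%-gap alignment row; C1
    a 98% cross-cell pair below the identity gate (kept). Family fam2
    carries the UTR-eligibility cases.
    """
    rng = np.random.default_rng(1729)
    a1 = _random_cds(rng, 100)
    a2 = _mutate_at(a1, range(24, 275, 25))
    a3_bg = _random_cds(rng, 100)
    a3 = a3_bg[:96] + a1[96:156] + a3_bg[156:]
    a4 = _random_cds(rng, 15)
    a5 = _random_cds(rng, 40)
    b1 = _mutate_at(a1, [200])
    b2 = _random_cds(rng, 100)
    b3 = _mutate_at(a1, [110, 230])
    c1 = _mutate_at(a1, [40, 90, 140, 190, 240, 285])
    d1 = _random_cds(rng, 65)
    f2_base = _random_cds(rng, 100)
    c2 = _mutate_at(f2_base, range(5, 291, 15))
    c3 = _mutate_at(f2_base, range(8, 294, 15))
    a6 = _mutate_at(f2_base, range(11, 297, 15))
    b4 = f2_base

    utr = lambda n, pat: (pat * (n // len(pat) + 1))[:n]
    spec = [
        # tid, cell, family, cds, cov, utr5, utr3
        ("A1", "cellA", "fam1", a1, 50.0, None, None),
        ("A2", "cellA", "fam1", a2, 8.0, None, None),
        ("A3", "cellA", "fam1", a3, 5.0, None, None),
        ("A4", "cellA", "fam1", a4, 40.0, None, None),
        ("A5", "cellA", "fam1", a5, 20.0, None, None),
        ("A6", "cellA", "fam2", a6, 35.0, utr(40, "ACAT"), utr(600, "TGTA")),
        ("B1", "cellB", "fam1", b1, 4.0, None, None),
        ("B2", "cellB", "fam1", b2, 30.0, None, None),
        ("B3", "cellB", "fam1", b3, 15.0, None, None),
        ("B4", "cellB", "fam2", b4, 45.0, None, None),
        ("C1", "cellC", "fam1", c1, 3.0, None, None),
        ("C2", "cellC", "fam2", c2, 25.0, utr(120, "ACCAT"), utr(200, "TGGTA")),
        ("C3", "cellC", "fam2", c3, 5.0, None, None),
        ("D1", "cellB", "fam1", d1, 12.0, None, None),
    ]
    records = {
        tid: TranscriptRecord(
            transcript_id=tid,
            cell_id=cell,
            gene_family_id=fam,
            cds=cds,
            utr5=u5,
            utr3=u3,
            kmer_coverage=cov,
        )
        for tid, cell, fam, cds, cov, u5, u3 in spec
    }
    width = 300
    rows1 = {
        tid: records[tid].cds + "-" * (width - len(records[tid].cds))
        for tid in ("A1", "A2", "A3", "A4", "A5", "B1", "B2", "B3", "C1", "D1")
    }
    rows2 = {tid: records[tid].cds for tid in ("A6", "B4", "C2", "C3")}
    alignments = {
        "fam1": GeneFamilyAlignment("fam1", rows1),
        "fam2": GeneFamilyAlignment("fam2", rows2),
    }
    return records, alignments
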