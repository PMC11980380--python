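"""End-to-end orchestration: curate -> profile -> analyze -> report.

Produces the figure-level tables for any dataset, simulated or real:
per-transcript composition, per-cell codon family frequencies and RSCU,
ENc (per transcript and pooled), amino-acid usage, stop-codon usage, SSDU,
expression regressions (per-codon frequency vs log TPM, GC4/GC12 vs log
TPM), neutrality-plot slopes by expression decile, and cross-taxon
amino-acid slopes. A failure inside one cell marks that cell failed and
leaves the others intact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import codon_usage as cu
from . import composition as comp
from . import expression as ex
from .curation import CurationConfig, CurationResult, curate
from .genetic_code import GeneticCode, build_standard_code
from .io import GeneFamilyAlignment, TranscriptRecord, write_tables
from .ssdu import (
    DINUCLEOTIDES,
    FRAME_POSITIONS,
    compute_ssdu,
    estimate_position_class_freqs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("silentbias_out")
    run_curation: bool = True
    curation: CurationConfig = field(default_factory=CurationConfig)
    enc_min_codons: int = 100
    ssdu_min_group: int = 10
    positional_window: int = 50
    bh_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["out_dir"] = str(self.out_dir)
        d["curation"] = dict(self.curation.__dict__)
        return d


@dataclass
class TaxonProfile:
    """Per-cell aggregate of codon counts and composition metrics."""

    cell_id: str
    codon_table: cu.CodonCountTable
    aa: cu.AminoAcidUsage
    stop_usage: Dict[str, float]
    median_gc4: float
    median_gc3s: float
    median_gc12: float
    median_enc: float
    mean_gc4: float
    mean_gc12: float
    bias_category: str
    pooled_enc: float
    utr5_gc: float
    utr3_gc: float
    n_transcripts: int


def transcript_length(rec: TranscriptRecord) -> int:
    """Raw transcript length: CDS plus any UTRs."""
    return len(rec.cds) + len(rec.utr5 or "") + len(rec.utr3 or "")


def per_transcript_table(
    records: Mapping[str, TranscriptRecord],
    code: Optional[GeneticCode] = None,
    enc_min_codons: int = 100,
) -> pd.DataFrame:
    """Composition and ENc metrics per transcript, plus TPM per cell.

    ENc is reported only for transcripts with at least ``enc_min_codons``
    analyzable codons (shorter genes give unstable family homozygosities).
    """
    code = code or build_standard_code()
    rows = []
    for tid in sorted(records):
        rec = records[tid]
        summary = comp.summarize_cds(rec.cds, code, rec.utr5, rec.utr3)
        table = cu.count_codons(rec.cds, code)
        enc = (
            cu.enc_observed(table, code).enc
            if summary.n_codons >= enc_min_codons
            else math.nan
        )
        rows.append(
            {
                "transcript_id": tid,
                "cell_id": rec.cell_id,
                "gene_family_id": rec.gene_family_id,
                "n_codons": summary.n_codons,
                "length": transcript_length(rec),
                "gc4": summary.gc4,
                "gc3s": summary.gc3s,
                "gc12": summary.gc12,
                "at_skew_silent": summary.at_skew_silent,
                "gc_skew_silent": summary.gc_skew_silent,
                "utr5_gc": summary.utr5_gc,
                "utr3_gc": summary.utr3_gc,
                "enc": enc,
                "kmer_coverage": rec.kmer_coverage,
                "read_count": rec.read_count,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["tpm"] = math.nan
    for cell, sub in df.groupby("cell_id"):
        counts = sub["read_count"].to_numpy(dtype=float)
        if np.all(np.isfinite(counts)) and counts.sum() > 0:
            df.loc[sub.index, "tpm"] = ex.tpm(counts, sub["length"].to_numpy(dtype=float))
    return df


def build_profile(
    cell_id: str,
    records: List[TranscriptRecord],
    per_transcript: pd.DataFrame,
    code: GeneticCode,
) -> TaxonProfile:
    table = cu.count_codons([r.cds for r in records], code, scope=cell_id)
    sub = per_transcript[per_transcript["cell_id"] == cell_id]
    eligible_u5 = [r.utr5 for r in records if r.utr5]
    eligible_u3 = [r.utr3 for r in records if r.utr3]
    median_gc4 = float(np.nanmedian(sub["gc4"])) if len(sub) else math.nan
    return TaxonProfile(
        cell_id=cell_id,
        codon_table=table,
        aa=cu.aa_usage(table, code),
        stop_usage=cu.stop_usage([table]),
        median_gc4=median_gc4,
        median_gc3s=float(np.nanmedian(sub["gc3s"])) if len(sub) else math.nan,
        median_gc12=float(np.nanmedian(sub["gc12"])) if len(sub) else math.nan,
        median_enc=float(np.nanmedian(sub["enc"])) if len(sub) else math.nan,
        mean_gc4=float(np.nanmean(sub["gc4"])) if len(sub) else math.nan,
        mean_gc12=float(np.nanmean(sub["gc12"])) if len(sub) else math.nan,
        bias_category=comp.classify_bias(median_gc4),
        pooled_enc=cu.enc_observed(table, code).enc,
        utr5_gc=comp.gc_fraction("".join(eligible_u5)) if eligible_u5 else math.nan,
        utr3_gc=comp.gc_fraction("".join(eligible_u3)) if eligible_u3 else math.nan,
        n_transcripts=len(records),
    )


def _family_freq_matrix(
    records: List[TranscriptRecord], code: GeneticCode
) -> pd.DataFrame:
    """Per-transcript within-family codon frequencies (NaN where the amino
    acid is absent from the transcript)."""
    tids = [r.transcript_id for r in records]
    counts = pd.DataFrame(0, index=tids, columns=list(code.sense_codons), dtype=float)
    for r in records:
        table = cu.count_codons(r.cds, code)
        for codon, n in table.counts.items():
            counts.at[r.transcript_id, codon] = n
    aa_of = {c: code.codon_to_aa[c] for c in code.sense_codons}
    totals = counts.T.groupby(aa_of).sum().T  # transcripts x amino acids
    freq = counts.copy()
    for codon in code.sense_codons:
        denom = totals[aa_of[codon]]
        freq[codon] = np.where(denom > 0, counts[codon] / denom, np.nan)
    return freq


def codon_slope_table(
    records: List[TranscriptRecord],
    per_transcript: pd.DataFrame,
    code: GeneticCode,
) -> pd.DataFrame:
    """Per-codon slope of family frequency on log10 TPM for one cell.

    Codons of single-codon families (ATG, TGG) are excluded; p-values are
    BH-corrected across the remaining 59 codons.
    """
    cell = records[0].cell_id
    freq = _family_freq_matrix(records, code)
    tpm_by_tid = per_transcript.set_index("transcript_id")["tpm"]
    tpms = tpm_by_tid.reindex(freq.index).to_numpy(dtype=float)
    results = {}
    for codon in code.sense_codons:
        if code.family_size(code.codon_to_aa[codon]) < 2:
            continue
        try:
            results[codon] = ex.metric_vs_log_tpm(freq[codon].to_numpy(), tpms)
        except ValueError:
            continue
    results = ex.attach_bh(results)
    rows = [
        {
            "cell_id": cell,
            "codon": codon,
            "amino_acid": code.codon_to_aa[codon],
            "slope": r.slope,
            "spearman_rho": r.spearman_rho,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "n": r.n,
        }
        for codon, r in sorted(results.items())
    ]
    return pd.DataFrame(rows)


def neutrality_table(per_transcript: pd.DataFrame) -> pd.DataFrame:
    """Neutrality-plot slopes (GC12 on GC4) per cell for all genes and the
    bottom/top expression deciles; BH across cells within each subset."""
    rows = []
    for subset in ("all", "bottom1", "top1"):
        per_cell: Dict[str, ex.RegressionResult] = {}
        for cell, sub in per_transcript.groupby("cell_id"):
            mask = np.ones(len(sub), dtype=bool)
            if subset != "all":
                try:
                    bins = ex.decile_bins(sub["tpm"].to_numpy(dtype=float))
                except ValueError:
                    continue
                mask = ex.decile_masks(bins)[subset]
            res = ex.neutrality_plot(
                sub["gc12"].to_numpy(), sub["gc4"].to_numpy(), mask
            )
            if not math.isnan(res.slope) or res.n:
                per_cell[cell] = res
        per_cell = ex.attach_bh(per_cell)
        for cell, r in sorted(per_cell.items()):
            rows.append(
                {
                    "cell_id": cell,
                    "subset": subset,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "spearman_rho": r.spearman_rho,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def expression_metric_table(per_transcript: pd.DataFrame) -> pd.DataFrame:
    """GC4 and GC12 vs log TPM per cell (BH across cells per metric)."""
    rows = []
    for metric in ("gc4", "gc12"):
        per_cell = {}
        for cell, sub in per_transcript.groupby("cell_id"):
            try:
                per_cell[cell] = ex.metric_vs_log_tpm(
                    sub[metric].to_numpy(), sub["tpm"].to_numpy()
                )
            except ValueError:
                continue
        per_cell = ex.attach_bh(per_cell)
        for cell, r in sorted(per_cell.items()):
            rows.append(
                {
                    "cell_id": cell,
                    "metric": metric,
                    "slope": r.slope,
                    "spearman_rho": r.spearman_rho,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def cross_taxon_table(
    records_by_cell: Mapping[str, List[TranscriptRecord]],
    per_transcript: pd.DataFrame,
    code: GeneticCode,
) -> pd.DataFrame:
    """Cross-taxon amino-acid-frequency slopes on mean GC4, for lowly
    (bottom two deciles) and highly (top two) expressed gene sets."""
    rows = []
    for subset in ("bottom2", "top2"):
        aa_rows = {}
        gc4_means = {}
        for cell, recs in records_by_cell.items():
            sub = per_transcript[per_transcript["cell_id"] == cell]
            try:
                bins = ex.decile_bins(sub["tpm"].to_numpy(dtype=float))
            except ValueError:
                continue
            mask = ex.decile_masks(bins)[subset]
            keep_ids = set(sub["transcript_id"].to_numpy()[mask])
            table = cu.count_codons(
                [r.cds for r in recs if r.transcript_id in keep_ids], code
            )
            usage = cu.aa_usage(table, code)
            aa_rows[cell] = usage.freqs
            gc4_means[cell] = float(np.nanmean(sub["gc4"]))
        if len(aa_rows) < 5:
            continue
        freq_df = pd.DataFrame(aa_rows).T
        results = ex.cross_taxon_aa_slopes(freq_df, gc4_means)
        for aa, r in sorted(results.items()):
            rows.append(
                {
                    "amino_acid": aa,
                    "subset": subset,
                    "slope": r.slope,
                    "spearman_rho": r.spearman_rho,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def analyze(
    records: Mapping[str, TranscriptRecord],
    config: Optional[PipelineConfig] = None,
    code: Optional[GeneticCode] = None,
) -> Dict[str, pd.DataFrame]:
    """Run every analysis stage on curated records; one table per stage."""
    cfg = config or PipelineConfig()
    code = code or build_standard_code()
    per_transcript = per_transcript_table(records, code, cfg.enc_min_codons)

    by_cell: Dict[str, List[TranscriptRecord]] = {}
    for tid in sorted(records):
        by_cell.setdefault(records[tid].cell_id, []).append(records[tid])

    profiles: Dict[str, TaxonProfile] = {}
    ssdu_rows, freq_rows, rscu_rows, enc_rows, aa_rows, stop_rows = [], [], [], [], [], []
    slope_tables = []
    failed_cells = []
    for cell in sorted(by_cell):
        recs = by_cell[cell]
        try:
            prof = build_profile(cell, recs, per_transcript, code)
            profiles[cell] = prof

            fam_freqs = cu.family_frequencies(prof.codon_table, code)
            rscu_vals = cu.rscu(prof.codon_table, code)
            for codon in code.sense_codons:
                freq_rows.append(
                    {
                        "cell_id": cell,
                        "codon": codon,
                        "amino_acid": code.codon_to_aa[codon],
                        "count": prof.codon_table.counts.get(codon, 0),
                        "family_frequency": fam_freqs[codon],
                    }
                )
                rscu_rows.append(
                    {"cell_id": cell, "codon": codon, "rscu": rscu_vals[codon]}
                )
            enc_rows.append(
                {
                    "cell_id": cell,
                    "scope": "cell",
                    "enc": prof.pooled_enc,
                    "median_transcript_enc": prof.median_enc,
                    "median_gc3s": prof.median_gc3s,
                }
            )
            for aa, f in sorted(prof.aa.freqs.items()):
                aa_rows.append({"cell_id": cell, "amino_acid": aa, "frequency": f})
            aa_rows.append(
                {"cell_id": cell, "amino_acid": "FYMINK", "frequency": prof.aa.fymink_frac}
            )
            aa_rows.append(
                {"cell_id": cell, "amino_acid": "GARP", "frequency": prof.aa.garp_frac}
            )
            for stop, f in sorted(prof.stop_usage.items()):
                stop_rows.append({"cell_id": cell, "stop_codon": stop, "frequency": f})

            cds_list = [r.cds for r in recs]
            freqs = estimate_position_class_freqs(cds_list, code)
            table = compute_ssdu(cds_list, freqs, code, cfg.ssdu_min_group)
            for h in DINUCLEOTIDES:
                for fp in FRAME_POSITIONS:
                    c = table.cells[(h, fp)]
                    ssdu_rows.append(
                        {
                            "cell_id": cell,
                            "dinucleotide": h,
                            "frame_position": fp,
                            "observed": c.observed,
                            "expected": c.expected,
                            "ssdu": c.ssdu,
                            "log2_ssdu": table.log2_ratio(h, fp),
                            "n_groups": c.n_groups,
                        }
                    )

            if per_transcript["tpm"].notna().any():
                slope_tables.append(codon_slope_table(recs, per_transcript, code))
        except Exception:  # pragma: no cover - per-cell isolation
            logger.exception("analysis failed for cell %s", cell)
            failed_cells.append(cell)

    by_taxon = pd.DataFrame(
        [
            {
                "cell_id": p.cell_id,
                "n_transcripts": p.n_transcripts,
                "median_gc4": p.median_gc4,
                "median_gc3s": p.median_gc3s,
                "median_gc12": p.median_gc12,
                "mean_gc4": p.mean_gc4,
                "mean_gc12": p.mean_gc12,
                "median_enc": p.median_enc,
                "pooled_enc": p.pooled_enc,
                "bias_category": p.bias_category,
                "utr5_gc": p.utr5_gc,
                "utr3_gc": p.utr3_gc,
                "hypothetical_gc12": cu.hypothetical_gc12(p.aa.freqs, code),
                "fymink_frac": p.aa.fymink_frac,
                "garp_frac": p.aa.garp_frac,
                "failed": p.cell_id in failed_cells,
            }
            for p in profiles.values()
        ]
    )

    tables: Dict[str, pd.DataFrame] = {
        "composition": per_transcript,
        "composition_by_taxon": by_taxon,
        "codon_frequencies": pd.DataFrame(freq_rows),
        "rscu": pd.DataFrame(rscu_rows),
        "enc": pd.DataFrame(enc_rows),
        "aa_usage": pd.DataFrame(aa_rows),
        "stop_usage": pd.DataFrame(stop_rows),
        "ssdu": pd.DataFrame(ssdu_rows),
    }
    if per_transcript["tpm"].notna().any():
        tables["codon_expression_slopes"] = (
            pd.concat(slope_tables, ignore_index=True) if slope_tables else pd.DataFrame()
        )
        tables["neutrality"] = neutrality_table(per_transcript)
        tables["regressions"] = expression_metric_table(per_transcript)
        cross = cross_taxon_table(by_cell, per_transcript, code)
        if len(cross):
            tables["aa_expression_slopes"] = cross
    return tables


def run_pipeline(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[PipelineConfig] = None,
) -> Tuple[Dict[str, pd.DataFrame], Optional[CurationResult]]:
    """Curate (optionally), analyze, and assemble the report bundle."""
    cfg = config or PipelineConfig()
    code = build_standard_code()
    curation_result = None
    if cfg.run_curation:
        pre = per_transcript_table(records, code, cfg.enc_min_codons)
        gc3s_by_tid = dict(zip(pre["transcript_id"], pre["gc3s"]))
        enc_by_tid = dict(zip(pre["transcript_id"], pre["enc"]))
        curation_result = curate(
            records, alignments, cfg.curation, gc3s_by_tid, enc_by_tid
        )
        records = curation_result.survivors

    tables = analyze(records, cfg, code)
    if curation_result is not None:
        tables["curation_log"] = pd.DataFrame(
            [
                {
                    "transcript_id": d.transcript_id,
                    "rule_id": d.rule_id,
                    "evidence": d.evidence,
                }
                for d in curation_result.decisions
            ],
            columns=["transcript_id", "rule_id", "evidence"],
        )
    return tables, curation_result


def write_report(
    tables: Mapping[str, pd.DataFrame], out_dir: Path
) -> List[Path]:
    return write_tables(tables, out_dir)
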