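"""Reading and writing of transcript data and analysis tables.

Inputs are plain text: FASTA for coding sequences (and optionally UTRs),
TSV for k-mer coverage / read counts and the taxon map. Records arrive
already in frame on the sense strand; loading validates frame, rejects
internal stops and N-heavy sequences, and stores a terminal stop (if
present) separately so it never enters codon statistics.

UTRs can be supplied either as extra FASTA records suffixed ``_utr5`` /
``_utr3`` or via a coordinate table over full transcripts (0-based
half-open columns ``cds_start``/``cds_end``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, build_standard_code

logger = logging.getLogger(__name__)

#: Transcripts with more than this fraction of N are rejected outright.
MAX_N_FRACTION = 0.10


@dataclass
class TranscriptRecord:
    """One coding sequence with optional UTRs and expression covariates."""

    transcript_id: str
    cell_id: str
    gene_family_id: str
    cds: str
    utr5: Optional[str] = None
    utr3: Optional[str] = None
    kmer_coverage: float = math.nan
    read_count: float = math.nan
    tpm: float = math.nan

    @property
    def has_coverage(self) -> bool:
        return not math.isnan(self.kmer_coverage)

    @property
    def n_codons(self) -> int:
        """Analyzable codons (terminal stop excluded)."""
        n = len(self.cds) // 3
        if n and self.cds[-3:].upper() in ("TAA", "TAG", "TGA"):
            n -= 1
        return n

    @property
    def terminal_stop(self) -> Optional[str]:
        tail = self.cds[-3:].upper()
        return tail if tail in ("TAA", "TAG", "TGA") else None


@dataclass
class GeneFamilyAlignment:
    """A gapped nucleotide alignment of one gene family."""

    gene_family_id: str
    rows: Dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"alignment {self.gene_family_id}: rows of unequal length {lengths}"
            )

    def ungapped(self, transcript_id: str) -> str:
        return self.rows[transcript_id].replace("-", "")

    def subset(self, keep: Iterable[str]) -> "GeneFamilyAlignment":
        keep = set(keep)
        return GeneFamilyAlignment(
            self.gene_family_id,
            {k: v for k, v in self.rows.items() if k in keep},
        )


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_rejected: int = 0
    n_missing_coverage: int = 0
    rejections: List[Tuple[str, str]] = field(default_factory=list)


class DuplicateTranscriptError(ValueError):
    pass


def _validate_cds(seq: str, code: GeneticCode) -> Optional[str]:
    """Return a rejection reason, or None if the CDS is analyzable."""
    if len(seq) % 3 != 0:
        return "length not divisible by 3"
    if not seq:
        return "empty sequence"
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        return f"non-ACGTN characters {sorted(bad)}"
    if seq.upper().count("N") / len(seq) > MAX_N_FRACTION:
        return "more than 10% N"
    codons = [seq[i : i + 3].upper() for i in range(0, len(seq), 3)]
    for c in codons[:-1]:
        if c in code.stop_set:
            return "internal stop"
    return None


def load_dataset(
    cds_fasta: Path,
    coverage_counts_tsv: Optional[Path] = None,
    taxon_map_tsv: Optional[Path] = None,
    utr_source: Optional[Path] = None,
    alignment_fastas: Optional[Mapping[str, Path]] = None,
    code: Optional[GeneticCode] = None,
) -> Tuple[Dict[str, TranscriptRecord], Dict[str, GeneFamilyAlignment], LoadReport]:
    """Assemble the record model from FASTA + TSV inputs.

    ``coverage_counts_tsv`` needs columns ``transcript_id``,
    ``kmer_coverage``, ``read_count``; ``taxon_map_tsv`` needs
    ``transcript_id``, ``cell_id`` and optionally ``gene_family_id`` (both
    default to FASTA header fields ``cell=``/``family=`` when absent).
    Records failing frame validation are rejected with a logged reason;
    a duplicate transcript id is a hard error.
    """
    code = code or build_standard_code()
    report = LoadReport()

    utr5_by_id: Dict[str, str] = {}
    utr3_by_id: Dict[str, str] = {}
    coords: Dict[str, Tuple[int, int]] = {}
    if utr_source is not None:
        utr_source = Path(utr_source)
        if utr_source.suffix.lower() in (".fa", ".fasta", ".fna"):
            for rec in SeqIO.parse(str(utr_source), "fasta"):
                if rec.id.endswith("_utr5"):
                    utr5_by_id[rec.id[: -len("_utr5")]] = str(rec.seq).upper()
                elif rec.id.endswith("_utr3"):
                    utr3_by_id[rec.id[: -len("_utr3")]] = str(rec.seq).upper()
        else:
            tab = pd.read_csv(utr_source, sep="\t")
            for _, row in tab.iterrows():
                coords[str(row["transcript_id"])] = (
                    int(row["cds_start"]),
                    int(row["cds_end"]),
                )

    cov: Dict[str, Tuple[float, float]] = {}
    if coverage_counts_tsv is not None:
        tab = pd.read_csv(coverage_counts_tsv, sep="\t")
        for _, row in tab.iterrows():
            cov[str(row["transcript_id"])] = (
                float(row["kmer_coverage"]),
                float(row["read_count"]),
            )

    taxon: Dict[str, Tuple[str, str]] = {}
    if taxon_map_tsv is not None:
        tab = pd.read_csv(taxon_map_tsv, sep="\t")
        for _, row in tab.iterrows():
            taxon[str(row["transcript_id"])] = (
                str(row["cell_id"]),
                str(row.get("gene_family_id", "")),
            )

    records: Dict[str, TranscriptRecord] = {}
    for rec in SeqIO.parse(str(cds_fasta), "fasta"):
        if rec.id.endswith(("_utr5", "_utr3")):
            continue
        tid = rec.id
        if tid in records:
            raise DuplicateTranscriptError(f"duplicate transcript id {tid!r}")
        seq = str(rec.seq).upper()
        utr5 = utr5_by_id.get(tid)
        utr3 = utr3_by_id.get(tid)
        if tid in coords:
            start, end = coords[tid]
            utr5, utr3 = seq[:start] or None, seq[end:] or None
            seq = seq[start:end]
        reason = _validate_cds(seq, code)
        if reason is not None:
            report.n_rejected += 1
            report.rejections.append((tid, reason))
            logger.info("rejected %s: %s", tid, reason)
            continue
        fields = dict(
            part.split("=", 1) for part in rec.description.split() if "=" in part
        )
        cell_id, family_id = taxon.get(
            tid, (fields.get("cell", "unknown"), fields.get("family", "unknown"))
        )
        if not family_id:
            family_id = fields.get("family", "unknown")
        coverage, count = cov.get(tid, (math.nan, math.nan))
        if math.isnan(coverage):
            report.n_missing_coverage += 1
        records[tid] = TranscriptRecord(
            transcript_id=tid,
            cell_id=cell_id,
            gene_family_id=family_id,
            cds=seq,
            utr5=utr5,
            utr3=utr3,
            kmer_coverage=coverage,
            read_count=count,
        )
    report.n_loaded = len(records)

    alignments: Dict[str, GeneFamilyAlignment] = {}
    if alignment_fastas:
        for fam, path in alignment_fastas.items():
            rows = {
                rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")
            }
            alignments[fam] = GeneFamilyAlignment(fam, rows)

    logger.info(
        "loaded %d records (%d rejected, %d missing coverage)",
        report.n_loaded,
        report.n_rejected,
        report.n_missing_coverage,
    )
    return records, alignments, report


def write_fasta(records: Iterable[TranscriptRecord], path: Path) -> None:
    """Write CDS (and any UTRs, suffixed) to FASTA, deterministic order."""
    recs = []
    for r in sorted(records, key=lambda r: r.transcript_id):
        recs.append(
            SeqRecord(
                Seq(r.cds),
                id=r.transcript_id,
                description=f"cell={r.cell_id} family={r.gene_family_id}",
            )
        )
        if r.utr5:
            recs.append(SeqRecord(Seq(r.utr5), id=r.transcript_id + "_utr5", description=""))
        if r.utr3:
            recs.append(SeqRecord(Seq(r.utr3), id=r.transcript_id + "_utr3", description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_metadata_tsvs(
    records: Iterable[TranscriptRecord], out_dir: Path
) -> Tuple[Path, Path]:
    """Write the coverage/counts and taxon-map TSVs next to a FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = sorted(records, key=lambda r: r.transcript_id)
    cov = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rows],
            "kmer_coverage": [r.kmer_coverage for r in rows],
            "read_count": [r.read_count for r in rows],
        }
    )
    tax = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rows],
            "cell_id": [r.cell_id for r in rows],
            "gene_family_id": [r.gene_family_id for r in rows],
        }
    )
    cov_path = out_dir / "coverage_counts.tsv"
    tax_path = out_dir / "taxon_map.tsv"
    cov.to_csv(cov_path, sep="\t", index=False, float_format="%.6f")
    tax.to_csv(tax_path, sep="\t", index=False)
    return cov_path, tax_path


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: Path) -> List[Path]:
    """Write analysis DataFrames as TSV with fixed precision and order.

    One file per analysis; an empty DataFrame still yields a headers-only
    file, and re-running on the same input is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(tables):
        df = tables[name]
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths.append(path)
    return paths
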