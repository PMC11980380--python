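"""Sequence-level curation for single-cell transcriptome assemblies.

The battery targets artifacts of short-read single-cell data: index-hopping
cross-contamination between cells on a plate (near-identical sequences with
asymmetric k-mer coverage), within-cell assembly duplicates, partial
transcripts, gappy alignment rows, and composition outliers. Rules run in a
fixed order -- cross-contamination, within-cell dedup, structural filters,
composition outliers, UTR eligibility -- and every removal is recorded as a
RemovalDecision so the curation log accounts for each dropped transcript.

Pairwise identity is computed from shared ungapped columns of the
gene-family alignment; the 50-bp exact-run test uses the longest common
substring of the unaligned sequences. "Clade average" length is the mean
ungapped length over the family's current members, iterated to a fixpoint
so the battery is idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np

from .io import GeneFamilyAlignment, TranscriptRecord

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    xcontam_identity: float = 0.99
    dup_identity: float = 0.95
    exact_run: int = 50
    short_frac: float = 0.25
    paralog_frac: float = 0.50
    gap_frac: float = 0.30
    cov_lo: float = 10.0
    partner_lo: float = 20.0
    cov_hi: float = 20.0
    partner_hi: float = 100.0
    clade_identity: float = 0.95
    outlier_z: float = 3.0
    outlier_min_transcripts: int = 20
    outlier_cov: float = 10.0
    utr_min_len: int = 50
    utr_max_len: int = 500


@dataclass
class RemovalDecision:
    transcript_id: str
    rule_id: str
    evidence: str = ""


def pairwise_identity(aln: GeneFamilyAlignment, id1: str, id2: str) -> float:
    """Matches over columns where both rows are ungapped; 0 if none shared."""
    r1, r2 = aln.rows[id1], aln.rows[id2]
    a = np.frombuffer(r1.encode(), dtype="S1")
    b = np.frombuffer(r2.encode(), dtype="S1")
    shared = (a != b"-") & (b != b"-")
    n = int(shared.sum())
    if n == 0:
        return 0.0
    return float((a[shared] == b[shared]).sum()) / n


def longest_common_run(s1: str, s2: str) -> int:
    """Length of the longest exact common substring of two sequences."""
    if not s1 or not s2:
        return 0
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    b = np.frombuffer(s2.encode(), dtype="S1")
    prev = np.zeros(len(s2), dtype=np.int32)
    best = 0
    for ch in s1:
        match = b == ch.encode()
        cur = np.zeros_like(prev)
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _family_members(
    records: Mapping[str, TranscriptRecord], aln: GeneFamilyAlignment
) -> List[str]:
    return sorted(t for t in aln.rows if t in records)


def flag_cross_contaminants(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[CurationConfig] = None,
) -> List[RemovalDecision]:
    """Flag members of near-identical (>=99%) cross-cell pairs with
    contaminant-like coverage.

    A flagged member has k-mer coverage <10 with a same-cell family partner
    above 20, or coverage <20 with a partner above 100. Candidates without
    coverage are skipped with a log line.
    """
    cfg = config or CurationConfig()
    decisions: Dict[str, RemovalDecision] = {}
    for fam in sorted(alignments):
        aln = alignments[fam]
        members = _family_members(records, aln)
        for i, t1 in enumerate(members):
            for t2 in members[i + 1 :]:
                r1, r2 = records[t1], records[t2]
                if r1.cell_id == r2.cell_id:
                    continue
                ident = pairwise_identity(aln, t1, t2)
                if ident < cfg.xcontam_identity:
                    continue
                for cand, other in ((r1, r2), (r2, r1)):
                    if cand.transcript_id in decisions:
                        continue
                    if not cand.has_coverage:
                        logger.info(
                            "cross-contamination candidate %s skipped: missing coverage",
                            cand.transcript_id,
                        )
                        continue
                    partners = [
                        records[t]
                        for t in members
                        if records[t].cell_id == cand.cell_id
                        and t != cand.transcript_id
                        and records[t].has_coverage
                    ]
                    rule = None
                    partner = None
                    for p in partners:
                        if cand.kmer_coverage < cfg.cov_lo and p.kmer_coverage > cfg.partner_lo:
                            rule, partner = "xcontam_10_20", p
                            break
                    if rule is None:
                        for p in partners:
                            if (
                                cand.kmer_coverage < cfg.cov_hi
                                and p.kmer_coverage > cfg.partner_hi
                            ):
                                rule, partner = "xcontam_20_100", p
                                break
                    if rule is not None:
                        decisions[cand.transcript_id] = RemovalDecision(
                            cand.transcript_id,
                            rule,
                            evidence=(
                                f"{ident:.4f} identical to {other.transcript_id} "
                                f"(cell {other.cell_id}); cov {cand.kmer_coverage:g} vs "
                                f"partner {partner.transcript_id} cov {partner.kmer_coverage:g}"
                            ),
                        )
    return list(decisions.values())


def dedup_within_cell(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[CurationConfig] = None,
) -> List[RemovalDecision]:
    """Remove the lower-coverage member of same-cell pairs that are >95%
    identical or share a 50-bp run of 100% identity.

    Coverage ties remove the shorter sequence, then the lexicographically
    later id. Pairs are visited in sorted order against the shrinking
    survivor set, so a transcript already removed cannot doom its partner.
    """
    cfg = config or CurationConfig()
    removed: Dict[str, RemovalDecision] = {}
    for fam in sorted(alignments):
        aln = alignments[fam]
        members = _family_members(records, aln)
        for i, t1 in enumerate(members):
            for t2 in members[i + 1 :]:
                if t1 in removed or t2 in removed:
                    continue
                r1, r2 = records[t1], records[t2]
                if r1.cell_id != r2.cell_id:
                    continue
                ident = pairwise_identity(aln, t1, t2)
                run = 0
                if ident <= cfg.dup_identity:
                    run = longest_common_run(r1.cds, r2.cds)
                if ident > cfg.dup_identity or run >= cfg.exact_run:
                    loser = _dedup_loser(r1, r2)
                    why = (
                        f"identity {ident:.4f}" if ident > cfg.dup_identity
                        else f"exact run {run} bp"
                    )
                    winner = t2 if loser is r1 else t1
                    removed[loser.transcript_id] = RemovalDecision(
                        loser.transcript_id,
                        "samecell_dup",
                        evidence=f"{why} with {winner} (cov {r1.kmer_coverage:g}/{r2.kmer_coverage:g})",
                    )
    return list(removed.values())


def _dedup_loser(r1: TranscriptRecord, r2: TranscriptRecord) -> TranscriptRecord:
    c1 = r1.kmer_coverage if r1.has_coverage else -math.inf
    c2 = r2.kmer_coverage if r2.has_coverage else -math.inf
    if c1 != c2:
        return r1 if c1 < c2 else r2
    if len(r1.cds) != len(r2.cds):
        return r1 if len(r1.cds) < len(r2.cds) else r2
    return max(r1, r2, key=lambda r: r.transcript_id)


def structural_filters(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[CurationConfig] = None,
) -> List[RemovalDecision]:
    """Length, paralog and gap-fraction filters per gene family.

    (a) transcripts shorter than 25% of the family mean ungapped length;
    (b) same-cell paralogs shorter than 50% of the mean; (c) all but the
    highest-coverage member of each same-cell >=95%-identity paralog group;
    (d) rows with >=30% gap columns. Length rules iterate to a fixpoint.
    Singleton families only see the gap rule.
    """
    cfg = config or CurationConfig()
    decisions: List[RemovalDecision] = []
    for fam in sorted(alignments):
        aln = alignments[fam]
        current: Set[str] = set(_family_members(records, aln))
        lengths = {t: len(aln.ungapped(t)) for t in current}

        if len(current) > 1:
            # (a) short transcripts, iterated
            while True:
                mean_len = np.mean([lengths[t] for t in current])
                short = sorted(
                    t for t in current if lengths[t] < cfg.short_frac * mean_len
                )
                if not short:
                    break
                for t in short:
                    decisions.append(
                        RemovalDecision(
                            t,
                            "short_25pct",
                            evidence=f"length {lengths[t]} < {cfg.short_frac:.2f} x family mean {mean_len:.1f}",
                        )
                    )
                    current.discard(t)
                if len(current) < 2:
                    break

        if len(current) > 1:
            # (b) short same-cell paralogs, iterated
            while True:
                mean_len = np.mean([lengths[t] for t in current])
                cells = {}
                for t in current:
                    cells.setdefault(records[t].cell_id, []).append(t)
                doomed = sorted(
                    t
                    for t in current
                    if len(cells[records[t].cell_id]) > 1
                    and lengths[t] < cfg.paralog_frac * mean_len
                )
                if not doomed:
                    break
                for t in doomed:
                    decisions.append(
                        RemovalDecision(
                            t,
                            "paralog_50pct",
                            evidence=f"length {lengths[t]} < {cfg.paralog_frac:.2f} x family mean {mean_len:.1f}",
                        )
                    )
                    current.discard(t)
                if len(current) < 2:
                    break

        if len(current) > 1:
            # (c) same-cell paralog groups: connected components of >=95%
            # identity pairs, keeping the highest-coverage representative.
            parent = {t: t for t in current}

            def find(t):
                while parent[t] != t:
                    parent[t] = parent[parent[t]]
                    t = parent[t]
                return t

            members = sorted(current)
            for i, t1 in enumerate(members):
                for t2 in members[i + 1 :]:
                    if records[t1].cell_id != records[t2].cell_id:
                        continue
                    if pairwise_identity(aln, t1, t2) >= cfg.clade_identity:
                        parent[find(t1)] = find(t2)
            groups: Dict[str, List[str]] = {}
            for t in members:
                groups.setdefault(find(t), []).append(t)
            for group in groups.values():
                if len(group) < 2:
                    continue
                keeper = max(
                    group,
                    key=lambda t: (
                        records[t].kmer_coverage if records[t].has_coverage else -math.inf,
                        lengths[t],
                        [-ord(ch) for ch in t],
                    ),
                )
                for t in sorted(group):
                    if t != keeper:
                        decisions.append(
                            RemovalDecision(
                                t,
                                "best_paralog",
                                evidence=f"paralog group kept {keeper} "
                                f"(cov {records[keeper].kmer_coverage:g})",
                            )
                        )
                        current.discard(t)

        # (d) gappy rows
        for t in sorted(current):
            row = aln.rows[t]
            frac = row.count("-") / len(row) if row else 0.0
            if frac >= cfg.gap_frac:
                decisions.append(
                    RemovalDecision(
                        t, "gap_30pct", evidence=f"gap fraction {frac:.2f}"
                    )
                )
                current.discard(t)
    return decisions


def robust_z(values: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 MAD); zeros when MAD is zero."""
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    if mad == 0 or np.isnan(mad):
        return np.zeros_like(values)
    return (values - med) / (1.4826 * mad)


def composition_outlier_filter(
    records: Mapping[str, TranscriptRecord],
    gc3s_by_tid: Mapping[str, float],
    enc_by_tid: Mapping[str, float],
    config: Optional[CurationConfig] = None,
) -> List[RemovalDecision]:
    """Remove GC3S/ENc outliers with low coverage or a better paralog.

    An outlier sits more than 3 robust-z units (median/MAD, per cell) from
    the cell's GC3S or ENc center; it is removed only when its coverage is
    below 10 or a same-cell, same-family non-outlying transcript with
    higher coverage exists. Cells with fewer than 20 transcripts are
    skipped.
    """
    cfg = config or CurationConfig()
    decisions: List[RemovalDecision] = []
    by_cell: Dict[str, List[str]] = {}
    for tid, rec in records.items():
        by_cell.setdefault(rec.cell_id, []).append(tid)
    for cell in sorted(by_cell):
        tids = sorted(by_cell[cell])
        if len(tids) < cfg.outlier_min_transcripts:
            logger.info(
                "outlier rule skipped for cell %s: only %d transcripts", cell, len(tids)
            )
            continue
        g = np.array([gc3s_by_tid.get(t, math.nan) for t in tids])
        e = np.array([enc_by_tid.get(t, math.nan) for t in tids])
        zg = robust_z(g)
        ze = robust_z(e)
        with np.errstate(invalid="ignore"):
            outlier = (np.abs(zg) > cfg.outlier_z) | (np.abs(ze) > cfg.outlier_z)
        outlier_ids = {t for t, o in zip(tids, outlier) if o}
        for t in sorted(outlier_ids):
            rec = records[t]
            cov_bad = rec.has_coverage and rec.kmer_coverage < cfg.outlier_cov
            better = [
                records[o]
                for o in tids
                if o not in outlier_ids
                and records[o].gene_family_id == rec.gene_family_id
                and records[o].has_coverage
                and rec.has_coverage
                and records[o].kmer_coverage > rec.kmer_coverage
            ]
            if cov_bad or better:
                why = "coverage < 10" if cov_bad else f"non-outlying paralog {better[0].transcript_id}"
                decisions.append(
                    RemovalDecision(
                        t,
                        "composition_outlier",
                        evidence=f"|z| > {cfg.outlier_z:g} (GC3S z={zg[tids.index(t)]:.1f}, "
                        f"ENc z={ze[tids.index(t)]:.1f}); {why}",
                    )
                )
    return decisions


def curate_utrs(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[CurationConfig] = None,
) -> Tuple[Dict[str, Dict[str, str]], List[RemovalDecision]]:
    """UTR eligibility: length in (50, 500) plus boundary support.

    A 5' UTR needs the CDS start methionine to align with a methionine in
    at least one other family row; a 3' UTR needs another row with a stop
    codon in the same alignment position. Absent UTRs are flagged absent,
    not ineligible.
    """
    cfg = config or CurationConfig()
    flags: Dict[str, Dict[str, str]] = {}
    decisions: List[RemovalDecision] = []
    aln_of: Dict[str, GeneFamilyAlignment] = {}
    for aln in alignments.values():
        for t in aln.rows:
            aln_of[t] = aln

    def _start_col(row: str) -> int:
        for i, ch in enumerate(row):
            if ch != "-":
                return i
        return -1

    def _stop_col(row: str, stops=("TAA", "TAG", "TGA")) -> int:
        ungapped_positions = [i for i, ch in enumerate(row) if ch != "-"]
        if len(ungapped_positions) < 3:
            return -1
        last3 = "".join(row[i] for i in ungapped_positions[-3:])
        return ungapped_positions[-3] if last3 in stops else -1

    for tid in sorted(records):
        rec = records[tid]
        f: Dict[str, str] = {}
        aln = aln_of.get(tid)
        for side, utr in (("utr5", rec.utr5), ("utr3", rec.utr3)):
            if not utr:
                f[side] = "absent"
                continue
            if not cfg.utr_min_len < len(utr) < cfg.utr_max_len:
                f[side] = "ineligible_length"
            elif aln is None or tid not in aln.rows:
                f[side] = "ineligible_no_alignment"
            elif side == "utr5":
                col = _start_col(aln.rows[tid])
                row = aln.rows[tid]
                own_met = row[col : col + 3] == "ATG"
                shared = any(
                    other != tid and aln.rows[other][col : col + 3] == "ATG"
                    for other in aln.rows
                )
                f[side] = "eligible" if own_met and shared else "ineligible_no_shared_met"
            else:
                col = _stop_col(aln.rows[tid])
                shared = col >= 0 and any(
                    other != tid and _stop_col(aln.rows[other]) == col
                    for other in aln.rows
                )
                f[side] = "eligible" if shared else "ineligible_no_shared_stop"
            if f[side].startswith("ineligible"):
                decisions.append(
                    RemovalDecision(
                        tid,
                        "utr_ineligible_5p" if side == "utr5" else "utr_ineligible_3p",
                        evidence=f[side],
                    )
                )
        flags[tid] = f
    return flags, decisions


@dataclass
class CurationResult:
    survivors: Dict[str, TranscriptRecord]
    decisions: List[RemovalDecision]
    utr_flags: Dict[str, Dict[str, str]]


def curate(
    records: Mapping[str, TranscriptRecord],
    alignments: Mapping[str, GeneFamilyAlignment],
    config: Optional[CurationConfig] = None,
    gc3s_by_tid: Optional[Mapping[str, float]] = None,
    enc_by_tid: Optional[Mapping[str, float]] = None,
) -> CurationResult:
    """Run the full battery in documented order and return survivors.

    The composition-outlier rule runs only when per-transcript GC3S/ENc
    values are supplied (the pipeline computes them before curating).
    """
    cfg = config or CurationConfig()
    current: Dict[str, TranscriptRecord] = dict(records)
    decisions: List[RemovalDecision] = []

    for stage in (flag_cross_contaminants, dedup_within_cell, structural_filters):
        stage_decisions = stage(current, alignments, cfg)
        decisions.extend(stage_decisions)
        for d in stage_decisions:
            current.pop(d.transcript_id, None)

    if gc3s_by_tid is not None and enc_by_tid is not None:
        outlier_decisions = composition_outlier_filter(
            current, gc3s_by_tid, enc_by_tid, cfg
        )
        decisions.extend(outlier_decisions)
        for d in outlier_decisions:
            current.pop(d.transcript_id, None)

    kept_alignments = {
        fam: aln.subset(current) for fam, aln in alignments.items()
    }
    utr_flags, utr_decisions = curate_utrs(current, kept_alignments, cfg)
    decisions.extend(utr_decisions)

    return CurationResult(survivors=current, decisions=decisions, utr_flags=utr_flags)
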