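"""Window re-alignment of unaligned sequences and SAM write-back.

The reference window around a putative site is the site extended by a
flank (default 100 bp) on each side, clipped to the chromosome.  The
group's sequence is re-aligned into the window with an exhaustive local
DP on both strands and accepted only when identity ≥ 0.85, query
coverage ≥ 0.64 (both inclusive, matching MegaBLAST's ``-perc_identity``
and ``-qcov_hsp_perc`` semantics) and the top score occurs at exactly
one locus in the window.  Accepted alignments are lifted back to genome
coordinates and written into the unmapped records of every member read
of the group; all other records stay byte-identical.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Optional

from .align import AlignerParams, LocalAlignment, align_in_window, compute_identity_coverage
from .artificial import UnalignedGroup
from .io import SamRecord, parse_cigar, reverse_complement, FLAG_UNMAPPED, FLAG_REVERSE
from .recovery import PutativeSite

RECOVERY_TAG = ("XV", "A", "R")
RECOVERED_MAPQ = 255  # mapping quality "unavailable": recovery is not calibrated


@dataclass(frozen=True)
class ReferenceWindow:
    chrom: str
    win_start: int
    win_end: int
    sequence: str


@dataclass(frozen=True)
class RecoveredAlignment:
    """The accepted re-alignment of one unaligned-sequence group."""

    group_id: int
    chrom: str
    pos: int  # 0-based genomic start of the aligned (non-clipped) part
    cigar: str  # full SAM cigar including soft clips, in stored orientation
    strand: str
    identity: float
    coverage: float
    spliced_path: bool


@dataclass
class RecoveryReport:
    total_reads: int = 0
    source_aligned: int = 0
    source_unaligned: int = 0
    recovered: int = 0

    @property
    def still_unaligned(self) -> int:
        return self.source_unaligned - self.recovered

    @property
    def pct_rescued(self) -> Optional[float]:
        if self.source_unaligned == 0:
            return None
        return 100.0 * self.recovered / self.source_unaligned

    def to_tsv(self) -> str:
        pct = "NA" if self.pct_rescued is None else f"{self.pct_rescued:.4f}"
        return (
            "total_reads\tsource_aligned\tsource_unaligned\trescued_reads\tpct_rescued\n"
            f"{self.total_reads}\t{self.source_aligned}\t{self.source_unaligned}"
            f"\t{self.recovered}\t{pct}\n"
        )


def extract_window(
    genome: dict[str, str], site: PutativeSite, flank: int = 100
) -> ReferenceWindow:
    """Slice the genome around a putative site, extended by ``flank`` and clipped."""
    chrom = site.interval.chrom
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    chrom_seq = genome[chrom]
    ws = max(0, site.interval.start - flank)
    we = min(len(chrom_seq), site.interval.end + flank)
    return ReferenceWindow(chrom, ws, we, chrom_seq[ws:we])


def _full_cigar(aln: LocalAlignment, query_len: int) -> str:
    """Add soft clips so the cigar consumes the whole stored sequence."""
    lead = aln.query_start
    trail = query_len - aln.query_end
    cigar = aln.cigar
    if lead:
        cigar = f"{lead}S{cigar}"
    if trail:
        cigar = f"{cigar}{trail}S"
    return cigar


def accepts_thresholds(
    identity: float, coverage: float,
    min_identity: float = 0.85, min_coverage: float = 0.64,
) -> bool:
    """Inclusive acceptance rule for re-aligned sequences."""
    return identity >= min_identity and coverage >= min_coverage


def realign_unspliced(
    group_sequence: str,
    window: ReferenceWindow,
    params: Optional[AlignerParams] = None,
    min_coverage: float = 0.64,
    min_identity: float = 0.85,
    group_id: int = 0,
    spliced_path: bool = False,
) -> Optional[RecoveredAlignment]:
    """Re-align a group sequence into a window; accept or return ``None``.

    Acceptance requires identity ≥ ``min_identity`` and coverage ≥
    ``min_coverage`` (inclusive) and a unique top score in the window.
    """
    aln_params = params if params is not None else AlignerParams(mode="realign_unspliced")
    best, n_top = align_in_window(str(group_id), group_sequence, window.sequence, aln_params)
    if best is None or n_top != 1:
        return None
    identity, coverage = compute_identity_coverage(best, len(group_sequence))
    if not accepts_thresholds(identity, coverage, min_identity, min_coverage):
        return None
    return RecoveredAlignment(
        group_id=group_id,
        chrom=window.chrom,
        pos=window.win_start + best.ref_start,
        cigar=_full_cigar(best, len(group_sequence)),
        strand=best.strand,
        identity=identity,
        coverage=coverage,
        spliced_path=spliced_path,
    )


def realign_spliced(
    group_sequence: str,
    window: ReferenceWindow,
    params: Optional[AlignerParams] = None,
    min_coverage: float = 0.64,
    min_identity: float = 0.85,
    group_id: int = 0,
) -> Optional[RecoveredAlignment]:
    """Spliced-site route.

    The builtin backend has no spliced model, so the alignment falls back
    to the unspliced window aligner and the result is flagged
    ``spliced_path`` for downstream scrutiny.  An external spliced-capable
    adapter (STAR) can replace this when configured.
    """
    return realign_unspliced(
        group_sequence, window, params, min_coverage, min_identity,
        group_id=group_id, spliced_path=True,
    )


def writeback(
    source_records: list[SamRecord],
    recovered: dict[int, RecoveredAlignment],
    groups: list[UnalignedGroup],
    mapq: int = RECOVERED_MAPQ,
    tag: tuple[str, str, str] = RECOVERY_TAG,
) -> tuple[list[SamRecord], RecoveryReport]:
    """Rewrite the unmapped records of recovered reads in place.

    Every member read of a recovered group gets the same coordinates,
    cigar and strand; minus-strand recoveries store the reverse-complement
    sequence with the reverse flag set, per SAM convention.  All other
    records are passed through untouched (byte-identical), and the record
    count is conserved.
    """
    group_by_id = {g.group_id: g for g in groups}
    target: dict[str, RecoveredAlignment] = {}
    for gid, rec_aln in recovered.items():
        group = group_by_id.get(gid)
        if group is None:
            raise ValueError(f"recovered group {gid} not among groups")
        for read_id in group.member_read_ids:
            target[read_id] = rec_aln

    mapped_reads: set[str] = set()
    unaligned_reads: set[str] = set()
    rewritten: set[str] = set()
    out: list[SamRecord] = []
    for rec in source_records:
        if not rec.is_unmapped:
            mapped_reads.add(rec.read_id)
            out.append(rec)
            continue
        unaligned_reads.add(rec.read_id)
        rec_aln = target.get(rec.read_id)
        if rec_aln is None:
            out.append(rec)
            continue
        out.append(_rewrite_record(rec, rec_aln, mapq, tag))
        rewritten.add(rec.read_id)

    missing = set(target) - rewritten - mapped_reads
    if missing:
        raise ValueError(
            f"recovered reads lack unmapped source records: {sorted(missing)[:5]}"
        )
    report = RecoveryReport(
        total_reads=len(mapped_reads | unaligned_reads),
        source_aligned=len(mapped_reads),
        source_unaligned=len(unaligned_reads),
        recovered=len(rewritten),
    )
    return out, report


def _rewrite_record(
    rec: SamRecord, rec_aln: RecoveredAlignment, mapq: int, tag: tuple[str, str, str]
) -> SamRecord:
    flags = rec.flags & ~FLAG_UNMAPPED & ~FLAG_REVERSE
    seq, qual = rec.sequence, rec.quality
    if rec_aln.strand == "-":
        flags |= FLAG_REVERSE
        if seq != "*":
            seq = reverse_complement(seq)
        if qual != "*":
            qual = qual[::-1]
    parse_cigar(rec_aln.cigar)  # validate before writing
    return rec.modified_copy(
        flags=flags,
        ref_name=rec_aln.chrom,
        pos0=rec_aln.pos,
        mapq=mapq,
        cigar=rec_aln.cigar,
        sequence=seq,
        quality=qual,
        tags=rec.tags + [tag],
    )


def write_sam_atomic(header: list[str], records, path) -> None:
    """Write a SAM file via a temp file and rename, so readers never see partials."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".sam.tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            for line in header:
                fh.write(line + "\n")
            for rec in records:
                fh.write(rec.to_line() + "\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
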