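"""Consensus filtering: from follow-up hits to putative genomic sites.

Every uniquely aligned read that aligns to an unaligned sequence in the
follow-up execution contributes its *source* genomic locus as a raw
interval.  Overlapping raw intervals are merged; a merged interval becomes
the putative site of the unaligned sequence when it holds more than one
supporting read and strictly more than ``threshold_frac`` (default 60%)
of all the sequence's supporters.  With a threshold of at least 0.5 at
most one interval can ever qualify.

An optional repeat filter drops unaligned sequences that align to a
repeat/low-complexity database at ≥90% identity and ≥80% coverage,
mirroring the tandem-repeat screen of the ROP tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .align import AlignerParams, builtin_align, compute_identity_coverage
from .artificial import ArtificialGenome, locate_bin
from .io import ReadRecord, SourceAlignment


@dataclass(frozen=True)
class FollowupHit:
    """A uniquely aligned read supporting one unaligned-sequence group."""

    group_id: int
    supporting_read_id: str
    source_location: SourceAlignment


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    support: int = 1
    spliced_support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not 0 <= self.spliced_support <= self.support:
            raise ValueError("spliced_support must be within [0, support]")


@dataclass(frozen=True)
class PutativeSite:
    group_id: int
    interval: GenomicInterval
    total_hits: int
    spliced: bool


def collect_followup_hits(
    followup_alignments,
    genome: ArtificialGenome,
    source_unique_index: dict[str, SourceAlignment],
) -> list[FollowupHit]:
    """Turn follow-up alignments on the artificial genome into per-group hits.

    An alignment yields a hit for the group whose bin it overlaps;
    alignments landing entirely in spacer are dropped.  A supporter
    counts at most once per group.
    """
    hits: list[FollowupHit] = []
    seen: set[tuple[int, str]] = set()
    for aln in followup_alignments:
        if aln.ref_name not in genome.chrom_sequences:
            raise KeyError(f"unknown artificial chromosome {aln.ref_name!r}")
        gid = locate_bin(genome, aln.ref_name, (aln.ref_start, aln.ref_end))
        if gid is None:
            continue
        read_id = aln.query_id
        src = source_unique_index.get(read_id)
        if src is None:
            continue  # supporter was not uniquely aligned in the source run
        key = (gid, read_id)
        if key in seen:
            continue
        seen.add(key)
        hits.append(FollowupHit(gid, read_id, src))
    return hits


def merge_intervals(raw_intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals per chromosome, summing supports.

    Intervals merely abutting (end == start) are not merged — overlap is
    strict under half-open semantics.  The result is idempotent,
    permutation-invariant, pairwise non-overlapping, and conserves the
    total support of the input.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in raw_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_support, cur_spliced = ivs[0].support, ivs[0].spliced_support
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict overlap
                cur_end = max(cur_end, iv.end)
                cur_support += iv.support
                cur_spliced += iv.spliced_support
            else:
                merged.append(
                    GenomicInterval(chrom, cur_start, cur_end, cur_support, cur_spliced)
                )
                cur_start, cur_end = iv.start, iv.end
                cur_support, cur_spliced = iv.support, iv.spliced_support
        merged.append(GenomicInterval(chrom, cur_start, cur_end, cur_support, cur_spliced))
    return merged


def consensus_filter(
    group_id: int,
    merged_intervals: list[GenomicInterval],
    total_hits: int,
    threshold_frac: float = 0.60,
) -> Optional[PutativeSite]:
    """Select the putative site for a group, or ``None``.

    An interval qualifies when its support exceeds 1 and strictly exceeds
    ``threshold_frac * total_hits``.  If a sub-majority threshold lets
    several intervals qualify, the highest support wins and a tie is
    ambiguous (``None``).
    """
    if total_hits <= 0:
        return None
    qualifying = [
        iv
        for iv in merged_intervals
        if iv.support > 1 and iv.support > threshold_frac * total_hits
    ]
    if not qualifying:
        return None
    qualifying.sort(key=lambda iv: -iv.support)
    if len(qualifying) > 1 and qualifying[0].support == qualifying[1].support:
        return None
    site_iv = qualifying[0]
    return PutativeSite(
        group_id=group_id,
        interval=site_iv,
        total_hits=total_hits,
        spliced=mark_spliced_interval(site_iv),
    )


def mark_spliced_interval(interval: GenomicInterval) -> bool:
    """A site is routed to the spliced re-aligner if any supporter was spliced."""
    return interval.spliced_support >= 1


def mark_spliced(site: PutativeSite) -> bool:
    return mark_spliced_interval(site.interval)


def sites_for_group(
    group_id: int,
    hits: list[FollowupHit],
    threshold_frac: float = 0.60,
) -> Optional[PutativeSite]:
    """Raw intervals from supporters' full source spans → merge → consensus."""
    group_hits = [h for h in hits if h.group_id == group_id]
    if not group_hits:
        return None
    raw = [
        GenomicInterval(
            h.source_location.chrom,
            h.source_location.start,
            h.source_location.end,
            support=1,
            spliced_support=1 if h.source_location.spliced else 0,
        )
        for h in group_hits
    ]
    return consensus_filter(
        group_id, merge_intervals(raw), len(group_hits), threshold_frac
    )


def repeat_filter(
    sequences: list[tuple[int, str]],
    repeat_db: dict[str, str],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
    params: Optional[AlignerParams] = None,
) -> list[tuple[int, str]]:
    """Drop sequences aligning to the repeat database at high identity/coverage.

    A sequence is removed iff some reported alignment reaches both
    ``min_identity`` and ``min_coverage``; everything else survives.  An
    empty database passes everything with a warning.
    """
    if not repeat_db or all(len(s) == 0 for s in repeat_db.values()):
        warnings.warn("repeat database is empty; repeat filter is a no-op")
        return list(sequences)
    aln_params = params if params is not None else AlignerParams(mode="followup", min_score_frac=0.2)
    surviving: list[tuple[int, str]] = []
    for sid, seq in sequences:
        alns = builtin_align([ReadRecord(str(sid), seq)], repeat_db, aln_params)
        repetitive = False
        for aln in alns:
            identity, coverage = compute_identity_coverage(aln, len(seq))
            if identity >= min_identity and coverage >= min_coverage:
                repetitive = True
                break
        if not repetitive:
            surviving.append((sid, seq))
    return surviving


def sites_to_bed(sites: Iterable[PutativeSite]) -> str:
    """Dump putative sites as BED lines (chrom, start, end, group_id, support)."""
    lines = [
        f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
        f"\t{s.group_id}\t{s.interval.support}"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
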