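"""End-to-end read-rescue pipeline and its configuration.

Stages, in order: source alignment (or ingestion of an existing SAM),
classification of reads into unique / multimapped / unaligned, grouping
of identical unaligned sequences, artificial-genome construction,
follow-up alignment of uniquely aligned reads against the artificial
genome, consensus filtering of the implied genomic intervals (plus the
optional repeat filter), window re-alignment, and SAM write-back.

The per-site consensus + re-alignment work is embarrassingly parallel;
``parallel_map`` provides the seam, and output ordering is by group id
regardless of the worker count so runs are byte-reproducible.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field
from typing import Optional

from .align import AlignerParams, KmerIndex, builtin_align
from .artificial import ArtificialGenome, UnalignedGroup, build_artificial_genome, group_identical_sequences
from .io import (
    Classification,
    ReadRecord,
    SamRecord,
    SourceAlignment,
    classify_alignments,
    make_sam_header,
    read_fasta,
    source_alignment_of,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
)
from .realign import (
    RecoveredAlignment,
    RecoveryReport,
    ReferenceWindow,
    extract_window,
    realign_spliced,
    realign_unspliced,
    writeback,
)
from .recovery import (
    FollowupHit,
    GenomicInterval,
    PutativeSite,
    collect_followup_hits,
    consensus_filter,
    merge_intervals,
    repeat_filter,
)

logger = logging.getLogger("readrescue")


@dataclass
class PipelineConfig:
    backend: str = "builtin"
    threshold_frac: float = 0.60
    flank: int = 100
    min_identity: float = 0.85
    min_coverage: float = 0.64
    repeat_min_identity: float = 0.90
    repeat_min_coverage: float = 0.80
    repeat_db: Optional[str] = None
    spacer_len: Optional[int] = None  # default: max(aligned read length, 100)
    bins_per_chrom: int = 10_000
    seed: int = 0
    n_workers: int = 1
    source_max_mismatch_frac: float = 0.04
    seed_len: int = 11
    followup_min_score_frac: float = 0.5

    def __post_init__(self) -> None:
        fracs = {
            "threshold_frac": self.threshold_frac,
            "min_identity": self.min_identity,
            "min_coverage": self.min_coverage,
            "repeat_min_identity": self.repeat_min_identity,
            "repeat_min_coverage": self.repeat_min_coverage,
        }
        for name, value in fracs.items():
            if not 0 < value <= 1:
                raise ValueError(f"{name} {value} outside (0, 1]")
        if self.backend not in ("builtin", "star", "blast"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class PipelineResult:
    header: list[str]
    records: list[SamRecord]
    report: RecoveryReport
    classification: Classification
    groups: list[UnalignedGroup]
    sites: dict[int, PutativeSite]
    recovered: dict[int, RecoveredAlignment]


# ---------------------------------------------------------------------------
# parallel seam
# ---------------------------------------------------------------------------

class _Call:
    """Picklable wrapper returning (ok, payload) so failures name their item."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, item):
        try:
            return True, self.fn(item)
        except Exception as exc:  # noqa: BLE001 - re-raised by parallel_map
            return False, f"{item!r}: {exc}"


def parallel_map(items, worker_fn, n_workers: int = 1) -> list:
    """Map a pure function over items; results in item order, any worker count."""
    items = list(items)
    if n_workers <= 1 or len(items) <= 1:
        return [worker_fn(item) for item in items]
    with multiprocessing.get_context("fork").Pool(n_workers) as pool:
        wrapped = pool.map(_Call(worker_fn), items)
    results = []
    for ok, payload in wrapped:
        if not ok:
            raise RuntimeError(f"worker failed on {payload}")
        results.append(payload)
    return results


def _realign_site(task) -> tuple[int, Optional[RecoveredAlignment]]:
    gid, seq, window, spliced, min_cov, min_ident = task
    if spliced:
        rec = realign_spliced(seq, window, None, min_cov, min_ident, group_id=gid)
    else:
        rec = realign_unspliced(seq, window, None, min_cov, min_ident, group_id=gid)
    return gid, rec


# ---------------------------------------------------------------------------
# source execution
# ---------------------------------------------------------------------------

def source_align(
    reads: list[ReadRecord],
    genome: dict[str, str],
    config: PipelineConfig,
) -> tuple[list[str], list[SamRecord]]:
    """Align reads with the builtin backend and emit source SAM records.

    A read is mapped only when it aligns end-to-end within the mismatch
    cap; ties for the top score make it multimapped (NH > 1, extra loci as
    secondary records).
    """
    params = AlignerParams(
        mode="source",
        max_mismatch_frac=config.source_max_mismatch_frac,
        seed_len=config.seed_len,
    )
    index = KmerIndex(genome, config.seed_len)
    header = make_sam_header(genome)
    records: list[SamRecord] = []
    for read in reads:
        hits = builtin_align([read], genome, params, index=index)
        if not hits:
            records.append(
                SamRecord(
                    read_id=read.read_id, flags=FLAG_UNMAPPED, ref_name=None,
                    pos0=None, mapq=0, cigar="*", rnext="*", pnext=0, tlen=0,
                    sequence=read.sequence,
                    quality=read.quality or "*",
                )
            )
            continue
        nh = len(hits)
        for rank, aln in enumerate(hits):
            flags = 0
            seq, qual = read.sequence, read.quality or "*"
            if aln.strand == "-":
                flags |= FLAG_REVERSE
                seq = _revcomp(seq)
                qual = qual[::-1] if qual != "*" else qual
            if rank > 0:
                flags |= FLAG_SECONDARY
            records.append(
                SamRecord(
                    read_id=read.read_id, flags=flags, ref_name=aln.ref_name,
                    pos0=aln.ref_start, mapq=255 if nh == 1 else 1,
                    cigar=aln.cigar, rnext="*", pnext=0, tlen=0,
                    sequence=seq if rank == 0 else "*",
                    quality=qual if rank == 0 else "*",
                    tags=[("NH", "i", str(nh))],
                )
            )
    return header, records


def _revcomp(seq: str) -> str:
    from .io import reverse_complement

    return reverse_complement(seq) if seq != "*" else seq


# ---------------------------------------------------------------------------
# recovery stages
# ---------------------------------------------------------------------------

def recover(
    header: list[str],
    records: list[SamRecord],
    genome: dict[str, str],
    config: PipelineConfig,
) -> PipelineResult:
    """Run follow-up, consensus, re-alignment and write-back on source records."""
    classification = classify_alignments(records)
    n_unique, n_multi, n_unaligned = classification.sizes()
    logger.info(
        "classification: %d unique, %d multimapped, %d unaligned",
        n_unique, n_multi, n_unaligned,
    )

    unaligned_reads = [
        ReadRecord(read_id, recs[0].sequence, None if recs[0].quality == "*" else recs[0].quality)
        for read_id, recs in classification.unaligned.items()
        if recs[0].sequence != "*"
    ]
    groups = group_identical_sequences(unaligned_reads)
    logger.info("grouped %d unaligned reads into %d groups", len(unaligned_reads), len(groups))
    if not groups or not classification.unique:
        report = RecoveryReport(
            total_reads=n_unique + n_multi + n_unaligned,
            source_aligned=n_unique + n_multi,
            source_unaligned=n_unaligned,
            recovered=0,
        )
        return PipelineResult(header, records, report, classification, groups, {}, {})

    followup_queries = [
        ReadRecord(read_id, rec.sequence, None if rec.quality == "*" else rec.quality)
        for read_id, rec in classification.unique.items()
        if rec.sequence != "*"
    ]
    max_query_len = max(len(r.sequence) for r in followup_queries)
    spacer = config.spacer_len if config.spacer_len is not None else max(max_query_len, 100)
    art = build_artificial_genome(
        groups, spacer, config.bins_per_chrom, max_query_len=max_query_len
    )

    followup_params = AlignerParams(
        mode="followup",
        seed_len=config.seed_len,
        min_score_frac=config.followup_min_score_frac,
    )
    followup_alns = builtin_align(followup_queries, art.chrom_sequences, followup_params)
    source_index = {
        read_id: source_alignment_of(rec, unique=True)
        for read_id, rec in classification.unique.items()
    }
    hits = collect_followup_hits(followup_alns, art, source_index)
    logger.info("follow-up: %d alignments -> %d hits", len(followup_alns), len(hits))

    hits_by_gid: dict[int, list[FollowupHit]] = {}
    for hit in hits:
        hits_by_gid.setdefault(hit.group_id, []).append(hit)

    sites: dict[int, PutativeSite] = {}
    for gid in sorted(hits_by_gid):
        group_hits = hits_by_gid[gid]
        raw = [
            GenomicInterval(
                h.source_location.chrom, h.source_location.start, h.source_location.end,
                support=1, spliced_support=1 if h.source_location.spliced else 0,
            )
            for h in group_hits
        ]
        site = consensus_filter(
            gid, merge_intervals(raw), len(group_hits), config.threshold_frac
        )
        if site is not None:
            sites[gid] = site
    logger.info("consensus: %d of %d groups with hits passed", len(sites), len(hits_by_gid))

    group_by_id = {g.group_id: g for g in groups}
    if config.repeat_db is not None:
        db = read_fasta(config.repeat_db)
        surviving = repeat_filter(
            [(gid, group_by_id[gid].sequence) for gid in sorted(sites)],
            db,
            config.repeat_min_identity,
            config.repeat_min_coverage,
        )
        keep = {gid for gid, _seq in surviving}
        dropped = len(sites) - len(keep)
        sites = {gid: site for gid, site in sites.items() if gid in keep}
        logger.info("repeat filter: removed %d sites", dropped)

    tasks = []
    for gid in sorted(sites):
        site = sites[gid]
        window = extract_window(genome, site, config.flank)
        tasks.append(
            (gid, group_by_id[gid].sequence, window, site.spliced,
             config.min_coverage, config.min_identity)
        )
    results = parallel_map(tasks, _realign_site, config.n_workers)
    recovered = {gid: rec for gid, rec in results if rec is not None}
    logger.info("re-alignment: %d of %d sites accepted", len(recovered), len(tasks))

    out_records, report = writeback(records, recovered, groups)
    logger.info(
        "write-back: %d of %d unaligned reads recovered",
        report.recovered, report.source_unaligned,
    )
    return PipelineResult(header, out_records, report, classification, groups, sites, recovered)


def run_pipeline(
    genome: dict[str, str],
    reads: Optional[list[ReadRecord]] = None,
    sam: Optional[tuple[list[str], list[SamRecord]]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Full pipeline from FASTQ reads or an existing SAM alignment."""
    if (reads is None) == (sam is None):
        raise ValueError("provide exactly one of reads or sam")
    cfg = config if config is not None else PipelineConfig()
    if reads is not None:
        header, records = source_align(reads, genome, cfg)
    else:
        header, records = sam
    return recover(header, records, genome, cfg)


def recovered_from_sam(records: list[SamRecord]) -> list[tuple[str, str, int, str]]:
    """(read_id, chrom, start, strand) of records carrying the recovery tag."""
    out = []
    for rec in records:
        if rec.tag_value("XV") == "R" and rec.ref_name is not None and rec.pos0 is not None:
            out.append(
                (rec.read_id, rec.ref_name, rec.pos0, "-" if rec.is_reverse else "+")
            )
    return out
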