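"""Aligner backends: one contract, a builtin implementation, and adapters.

The builtin backend is a deterministic seed-and-extend local aligner:
exact k-mer seeding on both strands followed by dynamic-programming
extension (match +1, mismatch −1, linear gap −2).  It serves three roles:

* **source** mode — semi-global alignment (query end-to-end, reference
  ends free), so a read is *mapped* only when its whole length aligns
  with a mismatch+gap fraction below a cap, and *unique* only when the
  top score occurs at exactly one locus;
* **followup** mode — local alignment, all loci above a score threshold
  reported, no splicing (the builtin never produces spliced alignments,
  which is exactly what the follow-up step requires);
* window re-alignment — exhaustive local DP inside a small reference
  window (see :func:`align_in_window`), where the unique-top-score rule
  is decided from the full DP matrix.

Adapters for STAR and MegaBLAST only render the tools' command lines;
executing them is opt-in and never required by the pipeline.

The DP kernels are compiled with numba; minus-strand alignments are
reported in the coordinates of the reverse-complemented query, matching
how SAM stores reverse-strand reads.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .io import ReadRecord, reverse_complement


@dataclass(frozen=True)
class LocalAlignment:
    """One gapped alignment of a query (or its reverse complement) to a reference."""

    query_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    cigar: str
    matches: int
    alignment_columns: int
    score: int


@dataclass
class AlignerParams:
    mode: str = "followup"  # source | followup | realign_unspliced | realign_spliced
    max_mismatch_frac: float = 0.04  # source mode: (mismatch+gap columns)/query_len cap
    report_all_hits: bool = True
    seed_len: int = 11
    seed_stride: int = 1
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    min_score_frac: float = 0.5  # followup mode reporting threshold

    def __post_init__(self) -> None:
        if self.mode == "followup":
            # the follow-up execution must see every candidate bin
            self.report_all_hits = True


# ---------------------------------------------------------------------------
# DP kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_local(q, r, match, mismatch, gap):
    n = q.shape[0]
    m = r.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if qi == r[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            if u > v:
                v = u
            w = H[i, j - 1] + gap
            if w > v:
                v = w
            if v < 0:
                v = 0
            H[i, j] = v
    return H


@njit(cache=True)
def _fill_qglobal(q, r, match, mismatch, gap):
    # query must be consumed end-to-end; leading/trailing reference is free
    n = q.shape[0]
    m = r.shape[0]
    H = np.empty((n + 1, m + 1), np.int32)
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if qi == r[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            if u > v:
                v = u
            w = H[i, j - 1] + gap
            if w > v:
                v = w
            H[i, j] = v
    return H


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _traceback(H, q, r, i, j, match, mismatch, gap, local: bool):
    """Walk back from cell (i, j); tie preference diagonal > up > left."""
    ops: list[str] = []
    matches = 0
    while i > 0 and (not local or H[i, j] > 0):
        if not local and j == 0:
            ops.append("I")
            i -= 1
            continue
        here = H[i, j]
        if j > 0:
            s = match if q[i - 1] == r[j - 1] else mismatch
            if here == H[i - 1, j - 1] + s:
                if q[i - 1] == r[j - 1]:
                    matches += 1
                ops.append("M")
                i -= 1
                j -= 1
                continue
        if here == H[i - 1, j] + gap:
            ops.append("I")
            i -= 1
            continue
        if j > 0 and here == H[i, j - 1] + gap:
            ops.append("D")
            j -= 1
            continue
        raise AssertionError("inconsistent DP matrix during traceback")
    ops.reverse()
    return i, j, ops, matches


def _ops_to_cigar(ops: Sequence[str]) -> str:
    parts = []
    run = 0
    last = ""
    for op in ops:
        if op == last:
            run += 1
        else:
            if run:
                parts.append(f"{run}{last}")
            last, run = op, 1
    if run:
        parts.append(f"{run}{last}")
    return "".join(parts)


def _extract_alignment(
    H, q, r, end_i, end_j, params: AlignerParams, local: bool
) -> tuple[int, int, int, int, str, int, int]:
    """Traceback from an end cell; returns (qs, qe, rs, re, cigar, matches, columns)."""
    qs, rs, ops, matches = _traceback(
        H, q, r, end_i, end_j, params.match, params.mismatch, params.gap, local
    )
    return qs, end_i, rs, end_j, _ops_to_cigar(ops), matches, len(ops)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer lookup over a reference; k-mers containing N are skipped."""

    def __init__(self, reference: dict[str, str], k: int):
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("empty reference")
        self.k = k
        self.chrom_names = list(reference.keys())
        self.chrom_seqs = [reference[c] for c in self.chrom_names]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(self.chrom_seqs):
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ci, pos))

    def candidate_starts(self, query: str, stride: int) -> dict[int, list[int]]:
        """Implied alignment start positions per chromosome, sorted, deduplicated."""
        k = self.k
        hits: dict[int, set[int]] = {}
        for off in range(0, len(query) - k + 1, stride):
            for ci, pos in self.index.get(query[off : off + k], ()):
                hits.setdefault(ci, set()).add(pos - off)
        return {ci: sorted(starts) for ci, starts in sorted(hits.items())}


def _cluster(starts: list[int], radius: int) -> list[tuple[int, int]]:
    """Merge sorted implied starts closer than ``radius`` into (min, max) clusters."""
    clusters: list[tuple[int, int]] = []
    lo = hi = starts[0]
    for s in starts[1:]:
        if s - hi <= radius:
            hi = s
        else:
            clusters.append((lo, hi))
            lo = hi = s
    clusters.append((lo, hi))
    return clusters


# ---------------------------------------------------------------------------
# builtin aligner
# ---------------------------------------------------------------------------

def builtin_align(
    queries: Iterable[ReadRecord],
    reference: dict[str, str],
    params: AlignerParams,
    index: Optional[KmerIndex] = None,
) -> list[LocalAlignment]:
    """Align queries against a reference with the builtin backend.

    In **source** mode only the top-scoring loci are returned, and nothing
    at all when the best alignment exceeds the mismatch cap — so a query is
    mapped iff it has output, and uniquely mapped iff that output has
    length one.  In **followup** mode every locus whose local score reaches
    ``min_score_frac * query_len`` is returned.  Output ordering is
    deterministic: per query, by descending score then reference
    coordinates.
    """
    idx = index if index is not None else KmerIndex(reference, params.seed_len)
    out: list[LocalAlignment] = []
    for read in queries:
        if len(read.sequence) < params.seed_len:
            raise ValueError(
                f"query {read.read_id!r} shorter than seed length {params.seed_len}"
            )
        out.extend(_align_one(read, idx, params))
    return out


def _align_one(read: ReadRecord, idx: KmerIndex, params: AlignerParams) -> list[LocalAlignment]:
    qlen = len(read.sequence)
    pad = max(8, qlen // 6)
    source_mode = params.mode == "source"
    results: dict[tuple, LocalAlignment] = {}
    for strand, qseq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        q = _encode(qseq)
        for ci, starts in idx.candidate_starts(qseq, params.seed_stride).items():
            ref_seq = idx.chrom_seqs[ci]
            for lo, hi in _cluster(starts, pad):
                ws = max(0, lo - pad)
                we = min(len(ref_seq), hi + qlen + pad)
                if we <= ws:
                    continue
                r = _encode(ref_seq[ws:we])
                aln = _window_best(
                    read.read_id, q, r, idx.chrom_names[ci], ws, strand, params,
                    local=not source_mode,
                )
                if aln is not None:
                    key = (aln.strand, aln.ref_name, aln.ref_start, aln.cigar)
                    prev = results.get(key)
                    if prev is None or aln.score > prev.score:
                        results[key] = aln
    hits = sorted(
        results.values(),
        key=lambda a: (-a.score, a.ref_name, a.ref_start, a.strand),
    )
    if source_mode:
        if not hits:
            return []
        top = hits[0].score
        best = [a for a in hits if a.score == top]
        errors = best[0].alignment_columns - best[0].matches
        if errors > params.max_mismatch_frac * qlen:
            return []
        return best
    min_score = params.min_score_frac * qlen
    return [a for a in hits if a.score >= min_score]


def _window_best(
    query_id: str,
    q: np.ndarray,
    r: np.ndarray,
    ref_name: str,
    ref_offset: int,
    strand: str,
    params: AlignerParams,
    local: bool,
) -> Optional[LocalAlignment]:
    if local:
        H = _fill_local(q, r, params.match, params.mismatch, params.gap)
        score = int(H.max())
        if score <= 0:
            return None
        end_i, end_j = _first_max_cell(H, score)
    else:
        H = _fill_qglobal(q, r, params.match, params.mismatch, params.gap)
        last = H[-1]
        score = int(last.max())
        end_i, end_j = H.shape[0] - 1, int(np.argmax(last))
    qs, qe, rs, re, cigar, matches, columns = _extract_alignment(
        H, q, r, end_i, end_j, params, local
    )
    if columns == 0:
        return None
    return LocalAlignment(
        query_id=query_id,
        ref_name=ref_name,
        ref_start=ref_offset + rs,
        ref_end=ref_offset + re,
        query_start=qs,
        query_end=qe,
        strand=strand,
        cigar=cigar,
        matches=matches,
        alignment_columns=columns,
        score=score,
    )


def _first_max_cell(H: np.ndarray, score: int) -> tuple[int, int]:
    cells = np.argwhere(H == score)
    return int(cells[0][0]), int(cells[0][1])


# ---------------------------------------------------------------------------
# exhaustive in-window alignment (re-alignment step)
# ---------------------------------------------------------------------------

def align_in_window(
    query_id: str,
    query_seq: str,
    window_seq: str,
    params: AlignerParams,
) -> tuple[Optional[LocalAlignment], int]:
    """Best local alignment of a query inside a reference window, both strands.

    No seeding: the full DP matrix is computed, so the second return value
    — the number of distinct (strand, end-cell) loci achieving the top
    score — is exact and implements the unique-top-score acceptance rule.
    """
    if not window_seq:
        return None, 0
    best_score = 0
    per_strand: dict[str, np.ndarray] = {}
    encoded: dict[str, np.ndarray] = {}
    rwin = _encode(window_seq)
    for strand, qseq in (("+", query_seq), ("-", reverse_complement(query_seq))):
        q = _encode(qseq)
        H = _fill_local(q, rwin, params.match, params.mismatch, params.gap)
        per_strand[strand] = H
        encoded[strand] = q
        best_score = max(best_score, int(H.max()))
    if best_score <= 0:
        return None, 0
    n_top = 0
    best_aln: Optional[LocalAlignment] = None
    for strand in ("+", "-"):
        H = per_strand[strand]
        cells = np.argwhere(H == best_score)
        n_top += len(cells)
        if len(cells) and best_aln is None:
            end_i, end_j = int(cells[0][0]), int(cells[0][1])
            qs, qe, rs, re, cigar, matches, columns = _extract_alignment(
                H, encoded[strand], rwin, end_i, end_j, params, local=True
            )
            best_aln = LocalAlignment(
                query_id=query_id, ref_name="window", ref_start=rs, ref_end=re,
                query_start=qs, query_end=qe, strand=strand, cigar=cigar,
                matches=matches, alignment_columns=columns, score=best_score,
            )
    return best_aln, n_top


def compute_identity_coverage(aln: LocalAlignment, query_len: int) -> tuple[float, float]:
    """identity = matches / alignment columns; coverage = aligned query span / query length."""
    if aln.alignment_columns == 0:
        raise ValueError("alignment with zero columns has no identity")
    identity = aln.matches / aln.alignment_columns
    coverage = (aln.query_end - aln.query_start) / query_len
    return identity, coverage


# ---------------------------------------------------------------------------
# external-tool command-line adapters
# ---------------------------------------------------------------------------

def star_followup_extra(num_reads: int) -> str:
    """Extra STAR flags for the follow-up execution: splicing disabled, hit cap lifted."""
    return (
        f"--outFilterMultimapNmax {num_reads} "
        "--alignIntronMax 1 --seedSearchStartLmax 30"
    )


def star_adapter_cmd(
    index_dir: str,
    read_files: str,
    out_prefix: str,
    threads: int = 1,
    extra: str = "",
) -> str:
    if not index_dir or not read_files or not out_prefix:
        raise ValueError("index_dir, read_files and out_prefix are all required")
    extra_part = f"{extra} " if extra else ""
    return (
        f"STAR --runThreadN {threads} {extra_part}--genomeDir {index_dir} "
        f"--readFilesIn {read_files} --outFileNamePrefix {out_prefix}"
    )


def blast_adapter_cmd(
    query: str,
    subject: str,
    identity: float,
    coverage: float,
    out: str,
) -> str:
    if not query or not subject or not out:
        raise ValueError("query, subject and out are all required")
    return (
        f"blastn -query {query} -subject {subject} -task megablast "
        f"-perc_identity {identity:g} -qcov_hsp_perc {coverage:g} "
        f'-outfmt "17 SQ SR" -out {out} -parse_deflines'
    )


def run_adapter(cmd: str, execute: bool = False) -> Optional[int]:
    """Render-only by default; with ``execute=True`` run the tool if present."""
    if not execute:
        return None
    binary = cmd.split()[0]
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"{binary!r} not found on PATH; install it or use the builtin backend"
        )
    return subprocess.run(cmd, shell=True, check=True).returncode
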