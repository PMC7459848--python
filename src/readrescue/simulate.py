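"""Synthetic genome / read simulation with ground truth, and evaluation.

The simulator draws a uniform-random genome, then reads uniformly over
positions and strands.  Each read base is independently substituted with
probability ``snp_rate`` (a planted "polymorphism", its genomic position
recorded) and then with probability ``error_rate`` (a sequencing error).
Three named tiers emulate increasing divergence between sample and
reference — low, moderate and high polymorphism — which is the regime in
which false-negative non-alignment appears.  No transcript or splicing
structure is modelled; spliced code paths are exercised with hand-built
alignment fixtures instead.

Evaluation utilities score recovered alignments against the truth table
and count planted SNPs overlapping alignments (a bedtools-intersect
style utility).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional
import warnings

import numpy as np

from .io import ReadRecord, SourceAlignment, Variant, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: tier presets: increasing per-base polymorphism at fixed sequencing error
TIER_SNP_RATES = {"low": 0.005, "moderate": 0.02, "high": 0.06}
DEFAULT_ERROR_RATE = 0.002


@dataclass
class SimConfig:
    genome_len: int = 100_000
    n_reads: int = 5_000
    read_len: int = 100
    snp_rate: float = 0.005
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0
    tier_name: str = "low"

    def __post_init__(self) -> None:
        for name in ("snp_rate", "error_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.25:
                raise ValueError(f"{name} {rate} outside [0, 0.25]")
        if self.read_len > self.genome_len:
            raise ValueError("read_len exceeds genome_len")

    @classmethod
    def tier(cls, name: str, **kwargs) -> "SimConfig":
        return cls(snp_rate=TIER_SNP_RATES[name], tier_name=name, **kwargs)


@dataclass(frozen=True)
class TruthEntry:
    chrom: str
    true_start: int  # 0-based genomic start of the read's origin
    strand: str
    n_planted_snps: int
    n_errors: int
    snp_positions: tuple[int, ...] = ()  # genomic positions of planted SNPs


@dataclass
class SimTruth:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def __getitem__(self, read_id: str) -> TruthEntry:
        return self.entries[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self) -> str:
        lines = ["read_id\tchrom\ttrue_start\tstrand\tn_planted_snps\tn_errors\tsnp_positions"]
        for read_id, e in self.entries.items():
            pos = ",".join(map(str, e.snp_positions)) if e.snp_positions else "."
            lines.append(
                f"{read_id}\t{e.chrom}\t{e.true_start}\t{e.strand}"
                f"\t{e.n_planted_snps}\t{e.n_errors}\t{pos}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SimTruth":
        truth = cls()
        lines = text.strip().split("\n")
        for line in lines[1:]:
            read_id, chrom, start, strand, n_snps, n_err, pos = line.split("\t")
            positions = () if pos == "." else tuple(int(p) for p in pos.split(","))
            truth.entries[read_id] = TruthEntry(
                chrom, int(start), strand, int(n_snps), int(n_err), positions
            )
        return truth


@dataclass
class RecoveryEvaluation:
    n_recovered: int
    n_correct: int
    n_incorrect: int
    tolerance_bp: int

    @property
    def pct_correct(self) -> Optional[float]:
        if self.n_recovered == 0:
            return None
        return 100.0 * self.n_correct / self.n_recovered

    def to_tsv(self) -> str:
        pct = "NA" if self.pct_correct is None else f"{self.pct_correct:.4f}"
        return (
            "n_recovered\tn_correct\tn_incorrect\tpct_correct\ttolerance_bp\n"
            f"{self.n_recovered}\t{self.n_correct}\t{self.n_incorrect}"
            f"\t{pct}\t{self.tolerance_bp}\n"
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genome(genome_len: int, seed: int, chrom_name: str = "chr1") -> dict[str, str]:
    """A uniform-random A/C/G/T genome, deterministic per seed."""
    if genome_len < 1_000:
        raise ValueError("genome_len must be at least 1000")
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=genome_len)
    return {chrom_name: seq.tobytes().decode("ascii")}


def _mutate(base_codes: np.ndarray, mask: np.ndarray, rng) -> np.ndarray:
    """Substitute masked positions with a uniformly chosen different base."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return base_codes
    shift = rng.integers(1, 4, size=len(idx))
    lut = np.zeros(256, dtype=np.uint8)
    for code_i, b in enumerate(BASES):
        lut[b] = code_i
    cur = lut[base_codes[idx]]
    base_codes = base_codes.copy()
    base_codes[idx] = BASES[(cur + shift) % 4]
    return base_codes


def simulate_reads(
    genome: dict[str, str], config: SimConfig
) -> tuple[list[ReadRecord], SimTruth]:
    """Draw reads with planted SNPs and sequencing errors; keep full truth.

    SNPs are planted first, then errors, each an independent per-base
    Bernoulli substitution.  Qualities are uniformly high.  Planted-SNP
    genomic positions are recorded for the SNP-overlap analysis.
    """
    rng = np.random.default_rng(config.seed)
    (chrom, chrom_seq), = genome.items()
    codes = np.frombuffer(chrom_seq.encode("ascii"), dtype=np.uint8)
    max_start = len(chrom_seq) - config.read_len
    starts = rng.integers(0, max_start + 1, size=config.n_reads)
    minus = rng.random(config.n_reads) < 0.5
    reads: list[ReadRecord] = []
    truth = SimTruth()
    qual = "I" * config.read_len
    width = len(str(max(config.n_reads - 1, 1)))
    for i in range(config.n_reads):
        start = int(starts[i])
        strand = "-" if minus[i] else "+"
        frag = codes[start : start + config.read_len]
        snp_mask = rng.random(config.read_len) < config.snp_rate
        err_mask = rng.random(config.read_len) < config.error_rate
        mutated = _mutate(frag, snp_mask, rng)
        mutated = _mutate(mutated, err_mask, rng)
        seq = mutated.tobytes().decode("ascii")
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"read_{i:0{width}d}"
        snp_offsets = np.nonzero(snp_mask)[0]
        reads.append(ReadRecord(read_id, seq, qual))
        truth.entries[read_id] = TruthEntry(
            chrom=chrom,
            true_start=start,
            strand=strand,
            n_planted_snps=int(snp_mask.sum()),
            n_errors=int(err_mask.sum()),
            snp_positions=tuple(int(start + off) for off in snp_offsets),
        )
    return reads, truth


def planted_snp_variants(genome: dict[str, str], truth: SimTruth) -> list[Variant]:
    """Distinct planted-SNP sites as VCF-style variants (alt recorded as N)."""
    (chrom, chrom_seq), = genome.items()
    seen: set[int] = set()
    variants: list[Variant] = []
    for entry in truth.entries.values():
        for pos in entry.snp_positions:
            if pos in seen:
                continue
            seen.add(pos)
            variants.append(Variant(chrom, pos, chrom_seq[pos], "N"))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(
    recovered_alignments: Iterable[tuple[str, str, int, str]],
    truth: SimTruth,
    tolerance_bp: int = 10,
) -> RecoveryEvaluation:
    """Score recovered (read_id, chrom, start, strand) tuples against truth.

    A recovery is correct iff chromosome and strand match and the start is
    within ``tolerance_bp`` of the true origin.
    """
    n_correct = n_total = 0
    for read_id, chrom, start, strand in recovered_alignments:
        if read_id not in truth:
            raise KeyError(f"recovered read {read_id!r} absent from truth")
        entry = truth[read_id]
        n_total += 1
        if (
            chrom == entry.chrom
            and strand == entry.strand
            and abs(start - entry.true_start) <= tolerance_bp
        ):
            n_correct += 1
    return RecoveryEvaluation(n_total, n_correct, n_total - n_correct, tolerance_bp)


def count_snps_per_alignment(
    alignments: Iterable[SourceAlignment], variants: Iterable[Variant]
) -> dict[str, int]:
    """Per read, the number of SNVs whose position falls in [start, end)."""
    positions: dict[str, list[int]] = {}
    for v in variants:
        if len(v.ref_allele) == 1 and len(v.alt_allele) == 1:
            positions.setdefault(v.chrom, []).append(v.pos)
    for chrom_positions in positions.values():
        chrom_positions.sort()
    counts: dict[str, int] = {}
    for aln in alignments:
        pos = positions.get(aln.chrom, [])
        counts[aln.read_id] = bisect_left(pos, aln.end) - bisect_left(pos, aln.start)
    return counts


def sample_reads_for_snp_analysis(
    alignments: list[SourceAlignment],
    n: int = 1000,
    unspliced_only: bool = True,
    seed: int = 0,
) -> list[SourceAlignment]:
    """Uniform sample without replacement, deterministic per seed."""
    pool = [a for a in alignments if not (unspliced_only and a.spliced)]
    if not pool:
        warnings.warn("empty pool for SNP analysis sampling")
        return []
    rng = np.random.default_rng(seed)
    k = min(n, len(pool))
    chosen = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(chosen)]
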