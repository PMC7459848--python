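"""Artificial-genome construction for the follow-up alignment step.

Identical unaligned sequences are grouped, each group's sequence is placed
in a fixed-pitch *bin* (sequence left-justified, padded with ``N`` to the
pitch ``W + S`` where ``W`` is the longest group sequence and ``S`` the
spacer length), and bins are concatenated into artificial chromosomes.
Because every bin carries at least ``S`` spacer ``N`` bases after its real
sequence, no query of length ≤ ``S`` can bridge two bins — an aligned read
can only ever align to one unaligned sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .io import ReadRecord

CHROM_PREFIX = "rescue_art"


@dataclass(frozen=True)
class UnalignedGroup:
    """One distinct unaligned sequence and the read ids sharing it."""

    group_id: int
    sequence: str
    member_read_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_read_ids:
            raise ValueError(f"group {self.group_id} has no members")


@dataclass
class ArtificialGenome:
    chrom_sequences: dict[str, str]
    bins: dict[int, tuple[str, int, int]]  # group_id -> (chrom, offset, seq_len)
    bin_width: int
    spacer_len: int
    bins_per_chrom: int

    @property
    def pitch(self) -> int:
        return self.bin_width + self.spacer_len


def group_identical_sequences(unaligned_reads: Iterable[ReadRecord]) -> list[UnalignedGroup]:
    """Group reads whose sequences are exactly equal.

    Groups are ordered by first occurrence of their sequence and get dense
    ids starting from 0, so the layout of the artificial genome is a pure
    function of the input read order.
    """
    members: dict[str, list[str]] = {}
    for read in unaligned_reads:
        members.setdefault(read.sequence, []).append(read.read_id)
    return [
        UnalignedGroup(gid, seq, tuple(ids))
        for gid, (seq, ids) in enumerate(members.items())
    ]


def build_artificial_genome(
    groups: list[UnalignedGroup],
    spacer_len: int,
    bins_per_chrom: int = 10_000,
    max_query_len: Optional[int] = None,
) -> ArtificialGenome:
    """Lay the group sequences out into spacer-padded artificial chromosomes.

    ``spacer_len`` must be at least the longest follow-up query read, or a
    query could bridge two bins; pass ``max_query_len`` to have this checked.
    """
    if not groups:
        raise ValueError("cannot build an artificial genome from zero groups")
    if max_query_len is not None and spacer_len < max_query_len:
        raise ValueError(
            f"spacer_len {spacer_len} < max query length {max_query_len}: "
            "bridging not prevented"
        )
    width = max(len(g.sequence) for g in groups)
    pitch = width + spacer_len
    chroms: dict[str, str] = {}
    bins: dict[int, tuple[str, int, int]] = {}
    for chrom_idx in range(0, (len(groups) + bins_per_chrom - 1) // bins_per_chrom):
        chunk = groups[chrom_idx * bins_per_chrom : (chrom_idx + 1) * bins_per_chrom]
        name = f"{CHROM_PREFIX}_{chrom_idx}"
        parts = []
        for slot, group in enumerate(chunk):
            seq = group.sequence
            parts.append(seq + "N" * (pitch - len(seq)))
            bins[group.group_id] = (name, slot * pitch, len(seq))
        chroms[name] = "".join(parts)
    return ArtificialGenome(chroms, bins, width, spacer_len, bins_per_chrom)


def locate_bin(genome: ArtificialGenome, chrom: str, interval: tuple[int, int]) -> Optional[int]:
    """Map a half-open interval on an artificial chromosome to its group.

    Returns the group whose real-sequence region the interval overlaps, or
    ``None`` when the interval touches only spacer ``N``s.  For intervals no
    longer than the spacer, overlap with two bins is impossible by
    construction; if a longer interval does overlap two, the bin with the
    larger overlap wins (lower group id on a tie).
    """
    if chrom not in genome.chrom_sequences:
        raise KeyError(f"unknown artificial chromosome {chrom!r}")
    start, end = interval
    if start >= end:
        return None
    pitch = genome.pitch
    chrom_idx = int(chrom.rsplit("_", 1)[1])
    first_slot = max(0, start // pitch)
    last_slot = (end - 1) // pitch
    best: Optional[tuple[int, int]] = None  # (-overlap, group_id)
    for slot in range(first_slot, last_slot + 1):
        gid = chrom_idx * genome.bins_per_chrom + slot
        info = genome.bins.get(gid)
        if info is None:
            continue
        _, offset, seq_len = info
        overlap = min(end, offset + seq_len) - max(start, offset)
        if overlap > 0:
            key = (-overlap, gid)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def decode_bin(genome: ArtificialGenome, group_id: int) -> str:
    """Recover a group's sequence from the artificial chromosome text."""
    chrom, offset, seq_len = genome.bins[group_id]
    return genome.chrom_sequences[chrom][offset : offset + seq_len]


def bin_map_tsv(genome: ArtificialGenome) -> str:
    """Serialize the bin map (group_id, chrom, offset, length) for debugging."""
    lines = ["group_id\tchrom\toffset\tlength"]
    for gid in sorted(genome.bins):
        chrom, offset, seq_len = genome.bins[gid]
        lines.append(f"{gid}\t{chrom}\t{offset}\t{seq_len}")
    return "\n".join(lines) + "\n"
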