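"""Core domain types and minimal text I/O for FASTA, FASTQ, SAM and VCF.

Internal coordinates are 0-based half-open throughout; conversion to and
from SAM's and VCF's 1-based coordinates happens only inside the readers
and writers in this module.  SAM records keep the raw input line so that
records the pipeline does not touch round-trip byte-identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# SAM flag bits used by the pipeline
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: cigar operations that consume reference / query bases
_REF_OPS = set("MDN=X")
_QUERY_OPS = set("MIS=X")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: identifier, sequence and optional quality string."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class SamRecord:
    """One SAM alignment line.

    ``ref_name`` and ``pos0`` are ``None`` for unmapped records.  ``raw``
    holds the original tab-joined line when the record came from a file and
    has not been modified; ``to_line`` emits it verbatim in that case.
    """

    read_id: str
    flags: int
    ref_name: Optional[str]
    pos0: Optional[int]  # 0-based leftmost mapped position
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    sequence: str
    quality: str
    tags: list[tuple[str, str, str]] = field(default_factory=list)
    raw: Optional[str] = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    def tag_value(self, name: str) -> Optional[str]:
        for tag, _typ, value in self.tags:
            if tag == name:
                return value
        return None

    def to_line(self) -> str:
        if self.raw is not None:
            return self.raw
        rname = self.ref_name if self.ref_name is not None else "*"
        pos = self.pos0 + 1 if self.pos0 is not None else 0
        fields = [
            self.read_id,
            str(self.flags),
            rname,
            str(pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.sequence,
            self.quality,
        ]
        fields.extend(f"{t}:{y}:{v}" for t, y, v in self.tags)
        return "\t".join(fields)

    def modified_copy(self, **changes) -> "SamRecord":
        """Copy with ``raw`` dropped so the new field values are emitted."""
        rec = replace(self, **changes)
        rec.raw = None
        return rec


@dataclass(frozen=True)
class SourceAlignment:
    """The genomic locus a read occupied in the source execution.

    ``end`` is the exclusive end of the reference span, including any
    intron skips (``N`` cigar operations), so a spliced alignment spans
    its whole junction.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    spliced: bool
    unique: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: empty reference span")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant at a 0-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    if cigar == "*" or not cigar:
        raise ValueError("cannot parse an absent cigar")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"invalid cigar {cigar!r}")
    return [(int(n), o) for n, o in ops]


def cigar_ref_span(cigar: str) -> int:
    """Reference bases consumed by a cigar (M/D/N/=/X)."""
    return sum(n for n, o in parse_cigar(cigar) if o in _REF_OPS)


def cigar_query_span(cigar: str) -> int:
    """Query bases consumed by a cigar (M/I/S/=/X)."""
    return sum(n for n, o in parse_cigar(cigar) if o in _QUERY_OPS)


def is_spliced(cigar: str) -> bool:
    """True iff the cigar contains at least one reference-skip (N) op."""
    return any(o == "N" for _n, o in parse_cigar(cigar))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    seqs: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in seqs:
                    raise ParseError(f"{path}:{lineno}: duplicate sequence {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[ReadRecord]:
    """Yield reads from a 4-line-record FASTQ file, sequences upper-cased."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header line")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno + 2}: expected '+' separator line")
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}:{lineno + 3}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            read_id = header[1:].rstrip("\n").split()[0]
            yield ReadRecord(read_id, seq.upper(), qual)
            lineno += 3


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _parse_sam_record(line: str, lineno: int, path) -> SamRecord:
    cols = line.split("\t")
    if len(cols) < 11:
        raise ParseError(f"{path}:{lineno}: SAM record has {len(cols)} columns, need 11")
    try:
        flags = int(cols[1])
        pos1 = int(cols[3])
        mapq = int(cols[4])
        pnext = int(cols[7])
        tlen = int(cols[8])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer mandatory field: {exc}") from None
    unmapped = bool(flags & FLAG_UNMAPPED)
    ref_name = None if cols[2] == "*" or unmapped else cols[2]
    pos0 = None if pos1 == 0 or unmapped else pos1 - 1
    tags = []
    for col in cols[11:]:
        parts = col.split(":", 2)
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: malformed tag {col!r}")
        tags.append((parts[0], parts[1], parts[2]))
    rec = SamRecord(
        read_id=cols[0], flags=flags, ref_name=ref_name, pos0=pos0, mapq=mapq,
        cigar=cols[5], rnext=cols[6], pnext=pnext, tlen=tlen,
        sequence=cols[9], quality=cols[10], tags=tags, raw=line,
    )
    if not unmapped and rec.cigar != "*":
        qspan = cigar_query_span(rec.cigar)
        if rec.sequence != "*" and qspan != len(rec.sequence):
            raise ParseError(
                f"{path}:{lineno}: cigar consumes {qspan} query bases but "
                f"sequence has {len(rec.sequence)}"
            )
    return rec


def read_sam(path) -> tuple[list[str], list[SamRecord]]:
    """Read a text SAM file; returns (header lines, records).

    Mapped records naming a reference absent from the ``@SQ`` header lines
    are an error.
    """
    header: list[str] = []
    records: list[SamRecord] = []
    sq_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if records:
                    raise ParseError(f"{path}:{lineno}: header line after records")
                header.append(line)
                if line.startswith("@SQ"):
                    for fld in line.split("\t")[1:]:
                        if fld.startswith("SN:"):
                            sq_names.add(fld[3:])
                continue
            rec = _parse_sam_record(line, lineno, path)
            if rec.ref_name is not None and rec.ref_name not in sq_names:
                raise ParseError(
                    f"{path}:{lineno}: reference {rec.ref_name!r} missing from @SQ header"
                )
            records.append(rec)
    return header, records


def write_sam(header: list[str], records: Iterable[SamRecord], path) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def make_sam_header(ref_seqs: dict[str, str]) -> list[str]:
    header = ["@HD\tVN:1.6\tSO:unknown"]
    header.extend(f"@SQ\tSN:{name}\tLN:{len(seq)}" for name, seq in ref_seqs.items())
    return header


# ---------------------------------------------------------------------------
# alignment-record classification
# ---------------------------------------------------------------------------

@dataclass
class Classification:
    """Partition of reads into unique / multimapped / unaligned."""

    unique: dict[str, SamRecord]
    multimapped: dict[str, list[SamRecord]]
    unaligned: dict[str, list[SamRecord]]

    def sizes(self) -> tuple[int, int, int]:
        return len(self.unique), len(self.multimapped), len(self.unaligned)


def classify_alignments(records: Iterable[SamRecord]) -> Classification:
    """Partition alignment records per read into unique, multimapped, unaligned.

    A read is *unique* when it has exactly one non-secondary mapped record
    and that record's NH tag is absent or 1; *unaligned* when every record
    for it carries the unmapped flag; everything else is *multimapped*.
    The partition is exhaustive and disjoint.
    """
    by_read: dict[str, list[SamRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    unique: dict[str, SamRecord] = {}
    multimapped: dict[str, list[SamRecord]] = {}
    unaligned: dict[str, list[SamRecord]] = {}
    for read_id, recs in by_read.items():
        mapped = [r for r in recs if not r.is_unmapped]
        unmapped_primary = [r for r in recs if r.is_unmapped and not r.is_secondary]
        if mapped and unmapped_primary:
            raise ValueError(
                f"read {read_id!r} has both mapped and unmapped primary records"
            )
        if not mapped:
            unaligned[read_id] = recs
            continue
        primary = [r for r in mapped if not r.is_secondary]
        if len(primary) == 1:
            nh = primary[0].tag_value("NH")
            if nh is None or int(nh) == 1:
                unique[read_id] = primary[0]
                continue
        multimapped[read_id] = recs
    return Classification(unique, multimapped, unaligned)


def source_alignment_of(rec: SamRecord, unique: bool = True) -> SourceAlignment:
    """Build the genomic-locus summary of a mapped SAM record."""
    if rec.is_unmapped or rec.ref_name is None or rec.pos0 is None:
        raise ValueError(f"read {rec.read_id!r} is not mapped")
    span = cigar_ref_span(rec.cigar)
    return SourceAlignment(
        read_id=rec.read_id,
        chrom=rec.ref_name,
        start=rec.pos0,
        end=rec.pos0 + span,
        strand="-" if rec.is_reverse else "+",
        spliced=is_spliced(rec.cigar),
        unique=unique,
    )


# ---------------------------------------------------------------------------
# VCF (sites only)
# ---------------------------------------------------------------------------

def read_vcf(path) -> list[Variant]:
    """Read CHROM/POS/REF/ALT from a sites VCF; positions converted to 0-based."""
    variants: list[Variant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: VCF record has <5 columns")
            try:
                pos1 = int(cols[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer POS {cols[1]!r}") from None
            variants.append(Variant(cols[0], pos1 - 1, cols[3], cols[4]))
    return variants


def write_vcf(variants: Iterable[Variant], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\n")
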