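"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the alignment
oracle is a full-matrix Smith-Waterman scan (row recurrence with a
prefix-max closure for the horizontal gap term), interval merging is a
transitive-closure fixpoint, and the consensus oracle enumerates both
inequalities directly.
"""

from __future__ import annotations

import numpy as np

from readrescue.io import reverse_complement


def sw_scan(query: str, ref: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Exhaustive local-alignment scan of one orientation.

    Returns (best_score, sorted ref_end positions achieving it).
    """
    q = np.frombuffer(query.encode(), np.uint8)
    r = np.frombuffer(ref.encode(), np.uint8)
    m = len(r)
    penal = -gap * np.arange(m + 1)
    prev = np.zeros(m + 1, dtype=np.int64)
    best = 0
    ends: set[int] = set()
    for i in range(len(q)):
        sub = np.where(r == q[i], match, mismatch)
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        e = np.concatenate(([0], np.maximum(0, np.maximum(diag, up))))
        # close over horizontal gap moves: H[j] = max_{j'<=j} e[j'] + gap*(j-j')
        cur = np.maximum.accumulate(e + penal) - penal
        row_best = int(cur.max())
        if row_best > best:
            best = row_best
            ends = set(np.nonzero(cur == row_best)[0].tolist())
        elif row_best == best and best > 0:
            ends.update(np.nonzero(cur == row_best)[0].tolist())
        prev = cur
    return best, sorted(ends)


def sw_scan_both_strands(query: str, ref: str, **kw):
    """Best score over both orientations with the loci achieving it.

    Loci are (strand, ref_end) pairs; minus-strand alignments are scored
    on the reverse-complemented query against the forward reference.
    """
    best = 0
    loci: set[tuple[str, int]] = set()
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        score, ends = sw_scan(q, ref, **kw)
        if score > best:
            best = score
            loci = {(strand, e) for e in ends}
        elif score == best and best > 0:
            loci.update((strand, e) for e in ends)
    return best, loci


def merge_by_transitive_closure(raw):
    """Union-merge intervals via an O(n^2) overlap-closure fixpoint.

    ``raw`` is a list of (chrom, start, end, spliced) tuples with unit
    support; returns a set of (chrom, start, end, support, spliced_support).
    """
    components = [[iv] for iv in raw]
    changed = True
    while changed:
        changed = False
        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                if _components_overlap(components[i], components[j]):
                    components[i] = components[i] + components[j]
                    del components[j]
                    changed = True
                    break
            if changed:
                break
    out = set()
    for comp in components:
        chrom = comp[0][0]
        out.add(
            (
                chrom,
                min(iv[1] for iv in comp),
                max(iv[2] for iv in comp),
                len(comp),
                sum(1 for iv in comp if iv[3]),
            )
        )
    return out


def _components_overlap(a, b) -> bool:
    for c1, s1, e1, _ in a:
        for c2, s2, e2, _ in b:
            if c1 == c2 and s1 < e2 and s2 < e1:
                return True
    return False


def consensus_oracle(merged, total_hits: int, threshold_frac: float):
    """Enumerate both consensus inequalities over merged components.

    ``merged`` holds (chrom, start, end, support, spliced_support) tuples;
    returns the winning tuple or None following the highest-support /
    ambiguous-tie rules.
    """
    if total_hits <= 0:
        return None
    qualifying = [
        c for c in merged if c[3] > 1 and c[3] > threshold_frac * total_hits
    ]
    if not qualifying:
        return None
    qualifying.sort(key=lambda c: -c[3])
    if len(qualifying) > 1 and qualifying[0][3] == qualifying[1][3]:
        return None
    return qualifying[0]


def bin_overlap_scan(genome, chrom: str, start: int, end: int):
    """Linear scan over every bin for overlap with a half-open interval."""
    overlapping = []
    for gid, (bchrom, offset, seq_len) in genome.bins.items():
        if bchrom != chrom:
            continue
        if start < offset + seq_len and offset < end:
            overlapping.append((min(end, offset + seq_len) - max(start, offset), gid))
    if not overlapping:
        return None
    overlapping.sort(key=lambda t: (-t[0], t[1]))
    return overlapping[0][1]


def plant_mutations(seq: str, positions, alphabet: str = "ACGT") -> str:
    """Substitute each position with the next base in the alphabet cycle."""
    chars = list(seq)
    for pos in positions:
        chars[pos] = alphabet[(alphabet.index(chars[pos]) + 1) % 4]
    return "".join(chars)
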