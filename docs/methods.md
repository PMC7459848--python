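# Methods

## Problem and model

An aligner applied to RNA-seq data produces *false-negative
non-alignments*: reads that belong to the reference but are rejected,
mostly because the sequenced individual diverges from the reference
(polymorphism) or because of sequencing error. The pipeline recovers
such reads using only information already present in the run, through a
metamorphic relation between two aligner executions:

* if an unaligned read truly originates from locus *L*, then reads that
  *did* align near *L* should resemble it;
* therefore, aligning the confidently aligned reads against the
  unaligned sequences (the follow-up execution, with the unaligned
  sequences acting as the reference) reveals, for each unaligned
  sequence, a set of supporters whose own genomic loci vote for *L*.

The method assumes the source aligner is deterministic, that mapped
reads re-align to the same locus when re-presented, and that unmapped
reads stay unmapped — properties the builtin backend satisfies by
construction and which the test suite asserts explicitly.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_frac` | 0.60 | fraction of a sequence's supporters a merged interval must strictly exceed |
| `flank` | 100 bp | extension of the putative site on each side before re-alignment |
| `min_identity` | 0.85 | matching columns / alignment columns floor (inclusive) |
| `min_coverage` | 0.64 | aligned query span / query length floor (inclusive) |
| `repeat_min_identity` / `repeat_min_coverage` | 0.90 / 0.80 | removal thresholds of the optional repeat filter |
| `spacer_len` | max(aligned read length, 100) | N padding between bins; ≥ query length forbids bridging |
| `bins_per_chrom` | 10,000 | bins per artificial chromosome |
| `source_max_mismatch_frac` | 0.04 | mismatch+gap cap for a source-mode mapping |
| `followup_min_score_frac` | 0.5 | minimum local score (fraction of query length) for a follow-up hit |
| `seed_len` | 11 | exact k-mer seed length of the builtin aligner |

Decisions taken where the design was genuinely open:

* **Interval construction.** Each supporter contributes its full source
  reference span, including intron skips, as one raw interval; merging
  requires at least 1 bp of overlap under half-open semantics (abutting
  intervals stay separate). Support counts distinct supporting reads.
* **Consensus inequalities are strict** (`support > 1`,
  `support > threshold_frac·total`). With a threshold ≥ 0.5 at most one
  interval can qualify; if a user configures a sub-majority threshold
  and several qualify, the highest support wins and an exact tie is
  treated as ambiguous (no site).
* **Spliced routing.** A single spliced supporter routes the site to
  the spliced re-aligner: one junction-spanning supporter is evidence of
  a junction at the site. The builtin backend has no splice model, so
  the spliced route falls back to the unspliced window aligner and tags
  the result `spliced_path`; sites whose sequence truly spans a junction
  then fail the 0.64 coverage floor and are honestly left unrecovered
  unless an external spliced aligner (STAR adapter) is wired in.
* **Acceptance thresholds are inclusive** (≥), matching the semantics
  of MegaBLAST's `-perc_identity`/`-qcov_hsp_perc` filters whose role
  they play.
* **Uniqueness at every stage is "unique top score"**: a tie for the
  best source-mode locus makes a read multimapped; a tie for the best
  in-window score (two distinct end cells of the DP matrix at the
  maximum, either strand) rejects the re-alignment.
* **Write-back** clears the unmapped flag, sets coordinates, cigar
  (with soft clips so the whole stored sequence is consumed) and
  strand identically for every member read of the group;
  reverse-strand recoveries store the reverse-complemented sequence
  with the reverse flag set. Recovered records get MAPQ 255 (mapping
  quality uncalibrated) and tag `XV:A:R` so downstream tools can
  identify rescued reads; both are configurable. Mate flags of
  paired-end input are preserved but recovery treats reads as
  single-end.
* **Coordinates** are 0-based half-open internally; 1-based conversion
  happens only inside SAM/VCF I/O. Unmodified SAM records round-trip
  byte-identically because the raw input line is kept alongside the
  parsed fields.

## Builtin aligner

Exact k-mer seeding (k = 11, both strands) proposes candidate loci;
each candidate cluster is extended by full dynamic programming in a
padded window at match +1, mismatch −1, linear gap −2. Source mode uses
a semi-global recurrence (query consumed end-to-end, reference ends
free), so "mapped" means full-length alignment within the mismatch cap
— coverage is 1.0 by construction. Follow-up and re-alignment use local
(Smith-Waterman) recurrences; re-alignment skips seeding entirely and
computes the exhaustive DP over the whole window so the uniqueness rule
is exact. Traceback prefers diagonal over vertical over horizontal
moves, and candidate output is sorted by (score, chromosome, position,
strand), making every run reproducible bit-for-bit. Kernels are
numba-compiled; the test oracle is a separate pure-numpy full-matrix
scan using a prefix-max closure for the horizontal gap term, an
independent formulation of the same optimum.

The scoring scheme and cap are pragmatic defaults, not tuned claims:
the contract (deterministic, realignable, non-realignable, unique-top
-score) is what the rest of the pipeline relies on. Seeding means a
query whose longest exact match to the reference is shorter than k is
invisible — the intended behaviour for an aligner, and the reason the
simulator's boundary fixtures space their mutations to preserve a seed.
Adapters render the STAR and MegaBLAST command lines (follow-up extras
`--outFilterMultimapNmax`, `--alignIntronMax 1`,
`--seedSearchStartLmax 30`; MegaBLAST identity/coverage filters) for
running the external tools instead; execution is opt-in and no test
depends on the binaries.

## Simulator: what it emulates and what it does not

`simulate_genome` draws a uniform i.i.d. A/C/G/T genome;
`simulate_reads` draws read positions and strands uniformly, then plants
per-base substitutions at `snp_rate` (recorded with their genomic
positions, emulating strain polymorphism) followed by substitutions at
`error_rate` (sequencing error). Three tier presets — low 0.005,
moderate 0.02, high 0.06, all at error 0.002 — emulate increasing
divergence between sample and reference. Qualities are uniformly high.
Per-read truth (origin, strand, planted SNP positions, error count) is
retained, serialized as TSV, and planted SNPs export as a VCF for the
SNP-overlap analysis.

Not modelled: transcript structure and splicing (spliced code paths are
exercised with hand-built SAM fixtures), indels (substitutions only by
default), quality-dependent error profiles, coverage biases, repeats
and low-complexity tracts (a uniform random genome is almost
repeat-free, which is why recovered placements are essentially always
unique and correct). Consequently the passing end-to-end tests show the
*mechanism* is correct — supporters are found, consensus selects the
true locus, re-alignment lifts coordinates exactly, write-back is
conservative — not that real-genome recovery reaches any particular
accuracy: on real data, repeats and paralogy make window uniqueness and
the repeat filter do real work.

Study conditions used by the acceptance checks: 100 kb genome, 5,000
reads of 100 bp per tier, one CPU; this exercises thousands of
unaligned groups in the high tier while keeping a full three-tier run
under a minute.

## Numerical and degenerate-input choices

* Strict `>` in consensus, inclusive `≥` in re-alignment and repeat
  thresholds (boundary behaviour pinned by dedicated tests).
* `total_hits = 0` or an empty merged list yields no site; empty read
  input, an empty repeat database (warn, pass-through) and
  zero-unmapped SAMs are all no-ops rather than errors.
* Division guards: identity is undefined for zero-column alignments
  (error), percent-rescued and percent-correct are reported as `NA`
  when their denominators are zero.
* Bin lookup is O(1) pitch arithmetic; an interval longer than the
  spacer overlapping two bins (impossible for real follow-up queries)
  resolves to the larger overlap, lower group id on ties.
* Output SAM is written atomically (temp file + rename).

## Known limitations

Single-end semantics during write-back (mates are not re-paired); no
BAM/CRAM output; no NH-tag recomputation for pre-existing records; the
builtin backend cannot produce spliced recoveries; MAPQ of recovered
records is a constant, not a calibrated probability.
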