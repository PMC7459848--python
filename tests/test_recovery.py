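"""Consensus filtering: hit collection, interval merging, thresholds, repeat filter."""

import pytest

from readrescue import (
    GenomicInterval,
    ReadRecord,
    SourceAlignment,
    build_artificial_genome,
    collect_followup_hits,
    consensus_filter,
    group_identical_sequences,
    mark_spliced,
    merge_intervals,
    repeat_filter,
    sites_for_group,
)
from readrescue.align import LocalAlignment
from readrescue.recovery import FollowupHit, PutativeSite

from util_oracles import consensus_oracle, merge_by_transitive_closure, plant_mutations


def _iv(chrom, start, end, support=1, spliced=0):
    return GenomicInterval(chrom, start, end, support, spliced)


def _src(read_id, start=0, end=100, chrom="chr1", spliced=False):
    return SourceAlignment(read_id, chrom, start, end, "+", spliced, True)


def _fake_aln(query_id, chrom, start, end):
    return LocalAlignment(query_id, chrom, start, end, 0, end - start, "+",
                          f"{end - start}M", end - start, end - start, end - start)


@pytest.fixture()
def art_genome():
    reads = [ReadRecord(f"u{i}", "ACGTACGTACGTACGTACGT") for i in range(5)]
    # distinct sequences so each read is its own group
    reads = [
        ReadRecord(f"u{i}", plant_mutations(r.sequence, [i]))
        for i, r in enumerate(reads)
    ]
    return build_artificial_genome(group_identical_sequences(reads), spacer_len=25, bins_per_chrom=100)


class TestCollectHits:
    def test_alignment_in_bin_real_region_yields_hit(self, art_genome):
        chrom = next(iter(art_genome.chrom_sequences))
        pitch = art_genome.pitch
        aln = _fake_aln("s1", chrom, 3 * pitch + 2, 3 * pitch + 18)
        index = {"s1": _src("s1")}
        (hit,) = collect_followup_hits([aln], art_genome, index)
        assert hit.group_id == 3 and hit.supporting_read_id == "s1"

    def test_spacer_only_alignment_dropped(self, art_genome):
        chrom = next(iter(art_genome.chrom_sequences))
        aln = _fake_aln("s1", chrom, 20, 40)  # bin 0 real region is [0, 20)
        assert collect_followup_hits([aln], art_genome, {"s1": _src("s1")}) == []

    def test_unknown_chromosome_rejected(self, art_genome):
        with pytest.raises(KeyError):
            collect_followup_hits([_fake_aln("s1", "bogus", 0, 10)], art_genome, {})

    def test_supporter_counted_once_per_group(self, art_genome):
        chrom = next(iter(art_genome.chrom_sequences))
        alns = [_fake_aln("s1", chrom, 2, 18), _fake_aln("s1", chrom, 1, 15)]
        hits = collect_followup_hits(alns, art_genome, {"s1": _src("s1")})
        assert len(hits) == 1

    def test_matches_brute_force_bin_scan(self, art_genome, rng):
        from util_oracles import bin_overlap_scan

        chrom = next(iter(art_genome.chrom_sequences))
        clen = len(art_genome.chrom_sequences[chrom])
        index = {f"s{i}": _src(f"s{i}") for i in range(500)}
        alns, expected = [], set()
        for i in range(500):
            start = int(rng.integers(0, clen - 20))
            end = start + int(rng.integers(5, 21))
            alns.append(_fake_aln(f"s{i}", chrom, start, end))
            gid = bin_overlap_scan(art_genome, chrom, start, end)
            if gid is not None:
                expected.add((gid, f"s{i}"))
        hits = collect_followup_hits(alns, art_genome, index)
        assert {(h.group_id, h.supporting_read_id) for h in hits} == expected


class TestMergeIntervals:
    def test_overlap_chain_merges_with_support(self):
        merged = merge_intervals([_iv("c", 10, 50), _iv("c", 40, 90), _iv("c", 200, 250)])
        assert [(m.start, m.end, m.support) for m in merged] == [(10, 90, 2), (200, 250, 1)]

    def test_disjoint_inputs_unchanged(self):
        ivs = [_iv("c", 0, 10), _iv("c", 20, 30)]
        assert merge_intervals(ivs) == ivs

    def test_abutting_intervals_not_merged(self):
        merged = merge_intervals([_iv("c", 0, 10), _iv("c", 10, 20)])
        assert len(merged) == 2

    def test_chromosomes_never_mix(self):
        merged = merge_intervals([_iv("a", 0, 100), _iv("b", 50, 150)])
        assert len(merged) == 2

    def test_spliced_support_accumulates(self):
        merged = merge_intervals([_iv("c", 0, 50, 1, 1), _iv("c", 25, 75, 1, 0)])
        assert merged[0].spliced_support == 1 and merged[0].support == 2

    def test_permutation_invariance_and_closure_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 31))
            raw = []
            for _i in range(n):
                start = int(rng.integers(0, 500))
                raw.append(
                    ("chr1" if rng.random() < 0.7 else "chr2", start,
                     start + int(rng.integers(1, 120)), bool(rng.random() < 0.2))
                )
            ivs = [_iv(c, s, e, 1, int(sp)) for c, s, e, sp in raw]
            merged = merge_intervals(ivs)
            got = {(m.chrom, m.start, m.end, m.support, m.spliced_support) for m in merged}
            assert got == merge_by_transitive_closure(raw)
            # permutation invariance
            perm = [ivs[int(i)] for i in rng.permutation(n)]
            assert set(merge_intervals(perm)) == set(merged)
            # idempotence, disjointness, conservation
            assert merge_intervals(merged) == merged
            assert sum(m.support for m in merged) == n
            by_chrom = {}
            for m in merged:
                by_chrom.setdefault(m.chrom, []).append(m)
            for chrom_ivs in by_chrom.values():
                chrom_ivs.sort(key=lambda m: m.start)
                for a, b in zip(chrom_ivs, chrom_ivs[1:]):
                    assert a.end <= b.start


class TestConsensus:
    def test_majority_interval_selected(self):
        merged = [_iv("c", 0, 100, 7), _iv("c", 500, 600, 3)]
        site = consensus_filter(0, merged, total_hits=10)
        assert site is not None and site.interval.support == 7

    def test_strict_inequality_at_threshold(self):
        merged = [_iv("c", 0, 100, 3), _iv("c", 500, 600, 2)]
        assert consensus_filter(0, merged, total_hits=5) is None  # 3 > 3.0 is false

    def test_more_than_one_read_rule(self):
        merged = [_iv("c", 0, 100, 1), _iv("c", 500, 600, 1)]
        assert consensus_filter(0, merged, total_hits=2) is None

    def test_zero_hits_vacuous(self):
        assert consensus_filter(0, [], total_hits=0) is None

    def test_sub_majority_threshold_tie_is_ambiguous(self):
        merged = [_iv("c", 0, 100, 3), _iv("c", 500, 600, 3)]
        assert consensus_filter(0, merged, total_hits=10, threshold_frac=0.2) is None
        merged = [_iv("c", 0, 100, 4), _iv("c", 500, 600, 3)]
        site = consensus_filter(0, merged, total_hits=10, threshold_frac=0.2)
        assert site is not None and site.interval.support == 4

    def test_monotonic_in_threshold(self, rng):
        """Raising the threshold can only remove sites, never create them."""
        for _ in range(100):
            total = int(rng.integers(1, 21))
            supports = []
            left = total
            while left > 0:
                s = int(rng.integers(1, left + 1))
                supports.append(s)
                left -= s
            merged = [
                _iv("c", 1000 * i, 1000 * i + 10, s) for i, s in enumerate(supports)
            ]
            lo = consensus_filter(0, merged, total, threshold_frac=0.6)
            hi = consensus_filter(0, merged, total, threshold_frac=0.8)
            if lo is None:
                assert hi is None

    def test_agrees_with_two_inequality_oracle(self, rng):
        for _ in range(300):
            total_hits = int(rng.integers(1, 21))
            raw = []
            for _i in range(total_hits):
                start = int(rng.integers(0, 300))
                raw.append(("chr1", start, start + int(rng.integers(1, 100)), False))
            merged = merge_intervals([_iv(*r[:3]) for r in raw])
            got = consensus_filter(0, merged, total_hits)
            expected = consensus_oracle(
                merge_by_transitive_closure(raw), total_hits, 0.60
            )
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.interval.chrom, got.interval.start, got.interval.end,
                        got.interval.support) == expected[:4]


class TestSplicedRouting:
    def test_unspliced_site(self):
        site = PutativeSite(0, _iv("c", 0, 100, 7, 0), 10, False)
        assert mark_spliced(site) is False

    def test_single_spliced_supporter_routes_spliced(self):
        site = PutativeSite(0, _iv("c", 0, 100, 7, 1), 10, True)
        assert mark_spliced(site) is True

    def test_all_spliced(self):
        site = PutativeSite(0, _iv("c", 0, 100, 7, 7), 10, True)
        assert mark_spliced(site) is True

    def test_sites_for_group_builds_from_source_spans(self):
        hits = [
            FollowupHit(5, "s1", _src("s1", 100, 200)),
            FollowupHit(5, "s2", _src("s2", 150, 250, spliced=True)),
            FollowupHit(5, "s3", _src("s3", 180, 280)),
            FollowupHit(7, "s4", _src("s4", 0, 100)),
        ]
        site = sites_for_group(5, hits)
        assert site is not None
        assert (site.interval.start, site.interval.end) == (100, 280)
        assert site.total_hits == 3 and site.spliced
        assert sites_for_group(99, hits) is None


class TestRepeatFilter:
    @pytest.fixture()
    def repeat_db(self, small_genome):
        (_, seq), = small_genome.items()
        return {"rep1": seq[4000:4200]}

    def test_exact_repeat_removed(self, repeat_db):
        seq = repeat_db["rep1"][:100]
        assert repeat_filter([(0, seq)], repeat_db) == []

    def test_unrelated_sequence_passes(self, repeat_db):
        seq = "AC" * 50  # no shared 11-mer with a random database entry
        assert repeat_filter([(0, seq)], repeat_db) == [(0, seq)]

    def test_coverage_below_080_passes(self, repeat_db):
        # 79 bases copied from the repeat followed by a tail that mismatches
        # the repeat continuation at every position, so the local alignment
        # stops at exactly coverage 0.79 with full identity
        rep = repeat_db["rep1"]
        tail = plant_mutations(rep[129:150], range(21))
        seq = rep[50:129] + tail
        assert repeat_filter([(0, seq)], repeat_db) == [(0, seq)]

    def test_coverage_at_080_removed(self, repeat_db):
        rep = repeat_db["rep1"]
        tail = plant_mutations(rep[130:150], range(20))
        seq = rep[50:130] + tail
        assert repeat_filter([(0, seq)], repeat_db) == []

    def test_identity_boundary_conjunction(self, repeat_db):
        # 12 interior substitutions over 120 bases: identity exactly 0.90;
        # spacing leaves a 16-base exact run so seeding always succeeds
        base = repeat_db["rep1"][50:170]
        positions = [4, 13, 22, 31, 40, 49, 58, 67, 76, 85, 94, 103]
        twelve = plant_mutations(base, positions)
        thirteen = plant_mutations(twelve, [99])
        assert repeat_filter([(0, twelve)], repeat_db) == []  # identity 0.90, cov 1.0
        assert repeat_filter([(1, thirteen)], repeat_db) == [(1, thirteen)]  # 0.8917

    def test_empty_db_passes_all_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = repeat_filter([(0, "ACGT" * 10)], {})
        assert out == [(0, "ACGT" * 10)]
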