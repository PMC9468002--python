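"""Stage 1 + Stage 2 of the assembler: counting, filtering, path search."""

import numpy as np
import pytest

from dbgps.channel import ChannelParams, simulate_channel
from dbgps.decoder import (
    CapacityError,
    DecodeAbort,
    KmerTable,
    apply_cutoff,
    choose_k,
    count_kmers,
    estimate_sm,
    greedy_path_search,
    reconstruct_all,
    seed_kmers,
    select_path,
)
from dbgps.dna import arr_to_seq, code_of, seq_to_arr
from dbgps.strand import StrandLayout, build_strand, encode_index

from conftest import make_random_pool


class TestChooseK:
    def test_small_pools_take_smallest_k(self):
        assert choose_k(1) == 17
        assert choose_k(1000) == 17

    def test_larger_pools_need_larger_k(self):
        assert choose_k(40_000) > 17

    def test_monotone_in_pool_size(self):
        ks = [choose_k(n) for n in (1, 10, 10**3, 10**4, 10**5, 10**6, 10**7)]
        assert ks == sorted(ks)
        assert all(k % 2 == 1 and 17 <= k <= 33 for k in ks)

    def test_birthday_bound_calculation(self):
        # closed form at the boundary: for 1000 strands / k=17 the expected
        # collision count is far below 1% of the pool
        n_total = 1000 * (164 - 17 + 2)
        assert n_total * (n_total - 1) / (2 * 4**16) < 10


class TestCountKmers:
    def test_window_counts_both_orientations(self):
        table = count_kmers(["ACGTACGT"], k=4, trim_primers=False)
        # 5 forward windows + 5 reverse-complement windows (palindromic read)
        assert int(table.counts.sum()) == 10
        assert table.count_of("ACGT") == 4  # twice forward, twice reverse

    def test_short_reads_contribute_nothing(self):
        table = count_kmers(["ACG", "ACGTA"], k=5, trim_primers=False)
        assert int(table.counts.sum()) == 2  # only the 5-mer read, both strands

    def test_conservation_against_direct_summation(self, rng):
        reads = [arr_to_seq(rng.integers(0, 4, rng.integers(10, 80), dtype="u1"))
                 for _ in range(200)]
        k = 9
        table = count_kmers(reads, k, trim_primers=False)
        expected = sum(2 * max(0, len(r) - k + 1) for r in reads)
        assert int(table.counts.sum()) == expected

    def test_primer_trimming_leaves_core_windows(self, layout):
        rec = build_strand(5, "ACGT" * 35)
        table = count_kmers([rec.sequence], k=17, layout=layout, trim_primers=True)
        assert int(table.counts.sum()) == 2 * (164 - 17 + 1)
        assert table.count_of(rec.core[:17]) == 1


class TestApplyCutoff:
    def _noisy_table(self, rng):
        rec = build_strand(0, arr_to_seq(rng.integers(0, 4, 140, dtype="u1")))
        copies = [rec.core] * 10
        noisy = seq_to_arr(rec.core).copy()
        noisy[70] = (noisy[70] + 2) % 4
        copies.append(arr_to_seq(noisy))
        return rec, count_kmers(copies, 17, trim_primers=False)

    def test_cutoff_one_is_identity(self, rng):
        _rec, table = self._noisy_table(rng)
        assert len(apply_cutoff(table, 1)) == len(table)

    def test_cutoff_two_removes_noise_keeps_truth(self, rng):
        rec, table = self._noisy_table(rng)
        filtered = apply_cutoff(table, 2)
        core = rec.core
        for i in range(len(core) - 16):
            assert code_of(core[i : i + 17]) in filtered
        # noise k-mers appear only in the single noisy copy
        assert len(filtered) == 2 * (164 - 17 + 1)

    def test_auto_cutoff_on_bimodal_histogram(self, rng):
        _rec, table = self._noisy_table(rng)
        filtered = apply_cutoff(table, "auto", copies=10)
        assert 2 <= filtered.cutoff <= 5

    def test_empty_table_aborts(self, rng):
        _rec, table = self._noisy_table(rng)
        with pytest.raises(DecodeAbort):
            apply_cutoff(table, 1000)


class TestSeeding:
    def test_error_free_strand_has_single_seed(self, layout):
        rec = build_strand(9, "GATC" * 35)
        table = apply_cutoff(count_kmers([rec.core] * 2, 17, trim_primers=False), 2)
        seeds = seed_kmers(9, table, layout)
        assert seeds == [code_of(rec.core[:17])]

    def test_absent_index_yields_no_seed(self, layout):
        rec = build_strand(9, "GATC" * 35)
        table = apply_cutoff(count_kmers([rec.core] * 2, 17, trim_primers=False), 2)
        assert seed_kmers(10, table, layout) == []

    def test_k_at_most_index_len_uses_index_prefix(self):
        lay = StrandLayout()
        rec = build_strand(3, "A" * 140)
        table = count_kmers([rec.core], 16, trim_primers=False)
        seeds = seed_kmers(3, table, lay)
        assert seeds == [code_of(encode_index(3))]


class TestGreedyPathSearch:
    def test_error_free_single_strand_unique_path(self, layout):
        # a periodic payload would fork against itself; random payloads are
        # what the design filter admits
        rec = make_random_pool(5, seed=31)[4]
        table = apply_cutoff(count_kmers([rec.core] * 3, 17, trim_primers=False), 2)
        cands = greedy_path_search(seed_kmers(4, table, layout), table, 164)
        assert cands == [rec.core]

    def test_branch_point_doubles_candidates(self, layout):
        rec = make_random_pool(5, seed=32)[4]
        variant = seq_to_arr(rec.core).copy()
        variant[100] = (variant[100] + 1) % 4
        reads = [rec.core] * 2 + [arr_to_seq(variant)] * 2
        table = apply_cutoff(count_kmers(reads, 17, trim_primers=False), 2)
        cands = greedy_path_search(seed_kmers(4, table, layout), table, 164)
        assert len(cands) == 2
        assert rec.core in cands

    def test_matches_brute_force_on_tiny_instances(self):
        """Candidate sets equal exhaustive enumeration at core 24, k=6."""
        for trial in range(8):
            assert_oracle_equivalence(seed=trial)


def brute_force_paths(start: str, kmers: set, core_len: int) -> set:
    """Independent oracle: depth-first enumeration over string membership."""
    k = len(start)
    out = set()

    def extend(seq: str):
        if len(seq) == core_len:
            out.add(seq)
            return
        for b in "ACGT":
            if seq[-(k - 1):] + b in kmers:
                extend(seq + b)

    extend(start)
    return out


def assert_oracle_equivalence(seed: int, core_len: int = 24, k: int = 6):
    rng = np.random.default_rng(seed)
    core = arr_to_seq(rng.integers(0, 4, core_len, dtype=np.uint8))
    # three noisy copies at a high substitution rate to provoke branching
    reads = []
    for _ in range(3):
        arr = seq_to_arr(core).copy()
        mut = rng.random(core_len) < 0.1
        arr[mut] = (arr[mut] + rng.integers(1, 4, int(mut.sum()), dtype=np.uint8)) % 4
        reads.append(arr_to_seq(arr))
    table = count_kmers(reads, k, trim_primers=False)
    kmer_strings = {
        arr_to_seq(np.array([(c >> (2 * (k - 1 - i))) & 3 for i in range(k)], dtype=np.uint8))
        for c in table.filtered_codes.tolist()
    }
    start = core[:k]
    seeds = [code_of(start)] if code_of(start) in table else []
    got = set(greedy_path_search(seeds, table, core_len))
    want = brute_force_paths(start, kmer_strings, core_len) if seeds else set()
    assert got == want


class TestSelectPath:
    def test_unique_true_candidate_wins(self, layout):
        rec = build_strand(2, "CAGT" * 35)
        corrupt = ["C" + rec.core[1:], rec.core[:-1] + "A", rec.core[:80] + "T" + rec.core[81:]]
        corrupt = [c[:164] for c in corrupt]
        status, payload = select_path([rec.core] + corrupt, layout, m=2)
        assert status == "recovered" and payload == rec.payload

    def test_no_candidates_is_dead_end(self, layout):
        status, payload = select_path([], layout)
        assert status == "dead-end" and payload is None

    def test_two_passing_candidates_ambiguous(self, layout):
        a = build_strand(2, "CAGT" * 35)
        b = build_strand(2, "TTGA" * 35)
        status, payload = select_path([a.core, b.core], layout, m=2)
        assert status == "ambiguous" and payload is None


class TestReconstructAll:
    def test_error_free_pool_full_recovery(self):
        pool = make_random_pool(40, seed=2)
        res = simulate_channel(pool, ChannelParams(copies=3, revcomp=False, seed=1))
        rep = reconstruct_all(res.reads, indices=range(40), k=17, cutoff=2)
        assert rep.s_r == 1.0
        assert all(rep.payloads[r.m] == r.payload for r in pool)

    def test_missing_index_reported_dead_end(self):
        pool = make_random_pool(20, seed=3)
        res = simulate_channel(pool[1:], ChannelParams(copies=3, revcomp=False, seed=1))
        rep = reconstruct_all(res.reads, indices=range(20), k=17, cutoff=2)
        assert rep.status[0] == "dead-end"
        assert rep.s_r == 19 / 20

    def test_read_order_invariance(self, rng):
        pool = make_random_pool(25, seed=4)
        res = simulate_channel(
            pool, ChannelParams(copies=8, sub_rate=0.02, ins_rate=0.01,
                                del_rate=0.01, seed=9))
        reads = res.reads
        rep1 = reconstruct_all(reads, indices=range(25), k=17, cutoff=2)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        rep2 = reconstruct_all(perm, indices=reversed(range(25)), k=17, cutoff=2)
        assert rep1.payloads == rep2.payloads
        assert rep1.status == rep2.status


class TestCeiling:
    def test_sr_does_not_exceed_sm(self):
        """The path-intactness probability is an upper bound on realized
        recovery (matched channel, 3 sigma slack for sampling)."""
        pool = make_random_pool(100, seed=55)
        res = simulate_channel(
            pool, ChannelParams(copies=10, sub_rate=0.015, ins_rate=0.0075,
                                del_rate=0.0075, seed=56))
        rep = reconstruct_all(res.reads, indices=range(100), k=17, cutoff=2)
        s_m = estimate_sm(copies=10, sub_rate=0.015, ins_rate=0.0075,
                          del_rate=0.0075, reps=300, cutoff=2, k=17, seed=57)
        sigma = np.sqrt(s_m * (1 - s_m) * (1 / 100 + 1 / 300)) or 0.02
        assert rep.s_r <= s_m + 3 * max(sigma, 0.02)


class TestEstimateSm:
    def test_zero_error_is_certain(self):
        assert estimate_sm(copies=3, reps=30, cutoff=2, k=17, seed=0) == 1.0

    def test_copies_below_cutoff_is_zero(self):
        assert estimate_sm(copies=1, reps=10, cutoff=2, k=17, seed=0) == 0.0

    def test_monotone_in_rate_and_copies(self):
        """Common random numbers: ceiling falls with error rate, rises with
        copy number."""
        rates = [0.0, 0.02, 0.05, 0.09]
        vals = [
            estimate_sm(copies=10, sub_rate=r, reps=120, cutoff=2, k=17, seed=7)
            for r in rates
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        copies = [4, 8, 14, 22]
        vals_c = [
            estimate_sm(copies=c, sub_rate=0.04, reps=120, cutoff=2, k=17, seed=7)
            for c in copies
        ]
        assert all(a <= b for a, b in zip(vals_c, vals_c[1:]))
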