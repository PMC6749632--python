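from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pedcase._util import revcomp
from pedcase.breakpoints import (
    Breakpoint,
    classify_junction,
    copy_number_flag,
    depth_profile,
    dotplot,
    inversion_length,
    load_mask_bed,
)
from pedcase.simulate import (
    JunctionSimConfig,
    simulate_depth,
    simulate_junction,
)


class TestInversionLength:
    def test_case_coordinates(self):
        bp1 = Breakpoint("X", 82_271_052)
        bp2 = Breakpoint("X", 86_034_441)
        length, mb = inversion_length(bp1, bp2)
        assert length == 3_763_389
        assert mb == 3.8

    def test_adjacent_positions(self):
        length, mb = inversion_length(Breakpoint("X", 5), Breakpoint("X", 6))
        assert length == 1 and mb == 0.0

    def test_reversed_order_rejected(self):
        with pytest.raises(ValueError, match="after"):
            inversion_length(Breakpoint("X", 10), Breakpoint("X", 5))

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="translocation"):
            inversion_length(Breakpoint("X", 5), Breakpoint("1", 10))


class TestClassifyJunction:
    def test_duplicated_motif_is_mmbir(self):
        sj = simulate_junction(
            JunctionSimConfig(motif="GTACAAGAAACT", microhomology_length=12,
                              seed=1)
        )
        call = classify_junction(sj.ref_left_flank, sj.ref_right_flank,
                                 sj.junction_seq)
        assert call.duplicated_length == 12
        assert call.duplicated_segment == "GTACAAGAAACT"
        assert call.mechanism == "MMBIR_like"
        assert call.deleted_length == 0

    def test_single_base_deletion_is_nhej(self):
        sj = simulate_junction(
            JunctionSimConfig(deletion_length=1, deleted_bases="T", seed=2)
        )
        call = classify_junction(sj.ref_left_flank, sj.ref_right_flank,
                                 sj.junction_seq)
        assert call.deleted_length == 1
        assert call.deleted_bases == "T"
        assert call.mechanism == "NHEJ_like"

    def test_exact_join_is_blunt(self):
        sj = simulate_junction(JunctionSimConfig(seed=3))
        call = classify_junction(sj.ref_left_flank, sj.ref_right_flank,
                                 sj.junction_seq)
        assert call.mechanism == "blunt"
        assert (call.duplicated_length, call.deleted_length,
                call.inserted_bases) == (0, 0, "")

    def test_unanchored_junction_unresolved(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seqs = ["".join(rng.choice(list(bases), 100)) for _ in range(3)]
        call = classify_junction(seqs[0], seqs[1], seqs[2])
        assert call.mechanism == "unresolved"
        assert call.diagnostics

    @pytest.mark.parametrize(
        "cfg",
        [
            JunctionSimConfig(microhomology_length=5, seed=10),
            JunctionSimConfig(microhomology_length=2, seed=11),
            JunctionSimConfig(microhomology_length=1, seed=12),
            JunctionSimConfig(deletion_length=4, seed=13),
            JunctionSimConfig(insertion="GGATCC", seed=14),
            JunctionSimConfig(microhomology_length=3, deletion_length=2,
                              seed=15),
        ],
    )
    def test_round_trip_recovers_configured_signature(self, cfg):
        sj = simulate_junction(cfg)
        call = classify_junction(sj.ref_left_flank, sj.ref_right_flank,
                                 sj.junction_seq)
        assert call.duplicated_segment == sj.truth["duplicated_segment"]
        assert call.deleted_bases == sj.truth["deleted_bases"]
        assert call.inserted_bases == sj.truth["inserted_bases"]
        assert call.mechanism == sj.truth["mechanism"]

    def test_sub_threshold_homology_is_not_mmbir(self):
        sj = simulate_junction(
            JunctionSimConfig(microhomology_length=1, seed=20)
        )
        call = classify_junction(sj.ref_left_flank, sj.ref_right_flank,
                                 sj.junction_seq)
        assert call.duplicated_length == 1
        assert call.mechanism == "NHEJ_like"


class TestDotplot:
    def _random_seq(self, n, seed):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), n))

    def test_identical_sequences_full_diagonal(self):
        seq = self._random_seq(100, 1)
        hits = dotplot(seq, seq, word_size=10, both_strands=False)
        diagonal = [(i, i, "+") for i in range(1, 92)]
        assert [h for h in hits if h[0] == h[1]] == diagonal
        assert len(diagonal) == 100 - 10 + 1

    def test_self_dotplot_always_contains_diagonal(self):
        for seed in range(3):
            seq = self._random_seq(60, seed)
            hits = set(dotplot(seq, seq))
            assert all((i, i, "+") in hits for i in range(1, 52))

    def test_symmetric_under_swap_with_transposition(self):
        a, b = self._random_seq(200, 2), self._random_seq(200, 3)
        ab = dotplot(a, b)
        ba = dotplot(b, a)
        assert sorted((j, i, s) for i, j, s in ab) == sorted(ba)

    def test_revcomp_matches_only_on_reverse_strand(self):
        # fixed sequence with no incidental inverted repeat at word size 12
        seq = self._random_seq(100, 0)
        hits = dotplot(seq, revcomp(seq), word_size=12)
        assert hits  # the anti-diagonal must be found
        assert all(s == "-" for _, _, s in hits)
        n, w = 100, 12
        # anti-diagonal coordinates: j = n - i - w + 2
        assert all(j == n - i - w + 2 for i, j, s in hits)

    def test_n_never_matches(self):
        a = "ACGTACGT"
        hits = dotplot(a, "ACGTNCGT", word_size=4, both_strands=False)
        # words of b starting at 2..5 contain the N and can never match
        assert all(j == 1 for _, j, _ in hits)
        assert (1, 1, "+") in hits

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert dotplot("ACGT", "ACGTACGTACGT", word_size=10) == []

    def test_random_match_count_follows_uniform_expectation(self):
        """Forward matches between unrelated 500-mers occur at rate
        (L-w+1)^2 / 4^w; the total over 100 seeded pairs must fall within
        Poisson bounds."""
        from scipy import stats

        w, L = 10, 500
        lam_pair = (L - w + 1) ** 2 / 4 ** w
        total = 0
        for seed in range(100):
            a = self._random_seq(L, 1000 + seed)
            b = self._random_seq(L, 2000 + seed)
            total += len(dotplot(a, b, word_size=w, both_strands=False))
        lam = 100 * lam_pair
        lo, hi = stats.poisson.ppf([1e-6, 1 - 1e-6], lam)
        assert lo <= total <= hi


class TestDepthProfile:
    def test_constant_per_base_depth(self):
        df = pd.DataFrame(
            {"chrom": "X", "pos": np.arange(1, 30_001), "depth": 14}
        )
        prof = depth_profile(df, window=10_000)
        assert len(prof) == 3
        assert np.allclose(prof.means, 14.0)

    def test_window_inside_mask_flagged(self):
        df = pd.DataFrame(
            {"chrom": "X", "pos": np.arange(1, 30_001), "depth": 10}
        )
        prof = depth_profile(df, window=10_000, mask=[(10_001, 20_000)])
        assert list(prof.masked) == [False, True, False]

    def test_mask_bed_is_zero_based_half_open(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("X\t10000\t20000\n")
        assert load_mask_bed(bed) == [(10_001, 20_000)]

    def test_window_means_invariant_to_chunked_input(self):
        rng = np.random.default_rng(7)
        depth = rng.poisson(13.8, size=50_000)
        df = pd.DataFrame(
            {"chrom": "X", "pos": np.arange(1, 50_001), "depth": depth}
        )
        whole = depth_profile(df, window=10_000)
        chunks = pd.concat(
            [df.iloc[i : i + 7_500] for i in range(0, 50_000, 7_500)]
        )
        split = depth_profile(chunks, window=10_000)
        assert np.allclose(whole.means, split.means)

    def test_per_window_input_accepted(self):
        df, _ = simulate_depth(chrom_length=200_000, window=10_000, seed=1)
        prof = depth_profile(df, window=10_000)
        assert len(prof) == 20


class TestCopyNumberFlag:
    def test_uniform_profile_neutral(self):
        df = pd.DataFrame(
            {"chrom": "X",
             "start": np.arange(20, dtype=int) * 10_000 + 1,
             "mean": 13.8}
        )
        prof = depth_profile(df, window=10_000)
        res = copy_number_flag(prof, (50_001, 100_000))
        assert res["neutral"] and res["ratio"] == pytest.approx(1.0)

    def test_poisson_neutral_profile_stays_neutral(self):
        for seed in range(5):
            df, _ = simulate_depth(chrom_length=3_000_000, seed=seed)
            prof = depth_profile(df)
            res = copy_number_flag(prof, (1_000_001, 2_000_000))
            assert res["neutral"], res

    @pytest.mark.parametrize("fold", [0.5, 1.5])
    def test_planted_cnv_flagged(self, fold):
        interval = (1_000_001, 2_000_000)
        for seed in range(5):
            df, _ = simulate_depth(
                chrom_length=3_000_000,
                cnv_intervals=[(*interval, fold)],
                seed=seed,
            )
            prof = depth_profile(df)
            res = copy_number_flag(prof, interval)
            assert not res["neutral"], (fold, seed, res)
            assert res["ratio"] == pytest.approx(fold, rel=0.05)

    def test_masked_windows_excluded(self):
        df, _ = simulate_depth(chrom_length=1_000_000, seed=2)
        mask = [(400_001, 600_000)]
        prof = depth_profile(df, mask=mask)
        res = copy_number_flag(prof, (300_001, 700_000))
        assert res["n_windows_inside"] == 20  # 40 windows minus 20 masked

    def test_no_unmasked_window_inside_raises(self):
        df, _ = simulate_depth(chrom_length=1_000_000, seed=3)
        prof = depth_profile(df, mask=[(1, 1_000_000)])
        with pytest.raises(ValueError, match="inside"):
            copy_number_flag(prof, (1, 500_000))
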