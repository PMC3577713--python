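import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflpkit.simulate import ScenarioConfig, simulate_peak_tables, simulate_taxa
from trflpkit.trflp import (
    BinnedMatrix,
    BinningParams,
    ConsensusProfile,
    RunProfile,
    TRFLPProfiler,
    apply_percent_threshold,
    bin_frames,
    merge_duplicates,
    profiles_from_records,
    select_best_frame,
    size_gate,
    to_presence_absence,
    variable_percentage_threshold,
)


def run(peaks, sample="A", enzyme="CfoI"):
    return RunProfile(sample, enzyme, tuple(peaks))


def consensus(peaks, sample="A", enzyme="CfoI"):
    return ConsensusProfile(sample, enzyme, tuple(sorted(peaks)))


class TestMergeDuplicates:
    def test_peaks_within_tolerance_averaged(self):
        out = merge_duplicates(run([(100.2, 500)]), run([(100.5, 700)]), 0.5)
        assert out.peaks == ((100.35, 600.0),)

    def test_gap_beyond_tolerance_removes_both(self):
        out = merge_duplicates(run([(100.0, 500)]), run([(101.0, 500)]), 0.5)
        assert out.peaks == ()

    def test_identical_runs_idempotent(self):
        peaks = [(90.0, 100.0), (171.4, 900.0), (505.0, 50.0)]
        out = merge_duplicates(run(peaks), run(peaks), 0.5)
        assert out.peaks == tuple(peaks)
        assert out.total_fluorescence == pytest.approx(1050.0)

    def test_mismatched_sample_rejected(self):
        with pytest.raises(ValueError, match="share sample_id"):
            merge_duplicates(run([(100, 1)]), run([(100, 1)], sample="B"), 0.5)

    def test_greedy_prefers_closest_pair(self):
        # 100.3 is nearer to run2's 100.4 than 100.0 is; pairing must
        # use the smallest size difference first
        out = merge_duplicates(
            run([(100.0, 10), (100.3, 20)]), run([(100.4, 30)]), 0.5
        )
        assert out.peaks == ((100.35, 25.0),)

    @given(
        sizes1=st.lists(st.floats(80, 600), min_size=0, max_size=8),
        sizes2=st.lists(st.floats(80, 600), min_size=0, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_removes_singletons(self, sizes1, sizes2):
        r1 = run([(s, 100.0) for s in sorted(sizes1)])
        r2 = run([(s, 100.0) for s in sorted(sizes2)])
        ab = merge_duplicates(r1, r2, 0.5)
        ba = merge_duplicates(r2, r1, 0.5)
        assert np.allclose(
            [p[0] for p in ab.peaks], [p[0] for p in ba.peaks]
        ) and len(ab.peaks) == len(ba.peaks)
        # every consensus peak lies within tol/2 of a peak in each run
        for s, _ in ab.peaks:
            assert any(abs(s - x) <= 0.25 + 1e-9 for x in sizes1)
            assert any(abs(s - x) <= 0.25 + 1e-9 for x in sizes2)
        # a peak isolated from every peak of the other run never survives
        for s in sizes1:
            if all(abs(s - x) > 0.5 for x in sizes2):
                assert all(abs(s - p[0]) > 0.25 - 1e-9 for p in ab.peaks)


class TestSizeGate:
    def test_bounds_are_strict(self):
        prof = consensus([(80.0, 1), (80.1, 1), (599.9, 1), (600.0, 1)])
        assert [p[0] for p in size_gate(prof).peaks] == [80.1, 599.9]

    def test_identity_when_all_inside(self):
        prof = consensus([(100.0, 1), (200.0, 2)])
        assert size_gate(prof) == prof

    def test_all_outside_gives_empty_profile(self):
        out = size_gate(consensus([(10.0, 1), (700.0, 1)]))
        assert out.peaks == () and out.total_fluorescence == 0.0


class TestPercentThreshold:
    def test_threshold_from_input_total_strict(self):
        prof = consensus([(100, 980.0), (200, 10.0), (300, 10.0)])
        out = apply_percent_threshold(prof, 1.2)  # threshold = 12.0
        assert [p[1] for p in out.peaks] == [980.0]

    def test_peak_at_exact_percentage_excluded(self):
        prof = consensus([(100, 988.0), (200, 12.0)])  # 12 = 1.2% of 1000
        out = apply_percent_threshold(prof, 1.2)
        assert [p[1] for p in out.peaks] == [988.0]

    def test_single_peak_retained(self):
        prof = consensus([(100, 5.0)])
        assert apply_percent_threshold(prof, 50).peaks == prof.peaks

    def test_zero_pct_is_noop(self):
        prof = consensus([(100, 1.0), (200, 2.0)])
        assert apply_percent_threshold(prof, 0.0) == prof


class TestVariablePercentageThreshold:
    def test_independent_counts_return_smallest(self):
        profiles = [
            consensus([(100 + i, 50.0) for i in range(5)], sample=f"S{j}")
            for j in range(6)
        ]
        assert variable_percentage_threshold(profiles, (0.5, 1.0, 2.0)) == 0.5

    def test_singleton_grid_forced(self):
        profiles = [
            consensus([(100, 10.0 * (j + 1))], sample=f"S{j}") for j in range(3)
        ]
        assert variable_percentage_threshold(profiles, (1.2,)) == 1.2

    def test_requires_three_profiles(self):
        profiles = [consensus([(100, 1.0)], sample=f"S{j}") for j in range(2)]
        with pytest.raises(ValueError):
            variable_percentage_threshold(profiles, (1.0,))

    def test_removes_count_fluorescence_correlation(self, rng):
        # profiles loaded with more DNA carry extra small peaks whose
        # share is below 1%; above that cutoff the dependence vanishes
        profiles = []
        for j in range(40):
            total = float(rng.uniform(1_000, 10_000))
            peaks = [(100.0, 0.6 * total), (200.0, 0.3 * total)]
            n_small = int(total // 1500)
            for i in range(n_small):
                peaks.append((300.0 + 5 * i, 8.0))  # absolute-size noise
            profiles.append(consensus(peaks, sample=f"S{j}"))
        grid = tuple(np.round(np.arange(0.1, 3.01, 0.1), 10))
        chosen = variable_percentage_threshold(profiles, grid)
        from scipy import stats

        # brute-force oracle: chosen pct must be the first grid point
        # whose one-sided correlation test no longer rejects
        totals = np.array([p.total_fluorescence for p in profiles])
        for pct in grid:
            counts = np.array(
                [len(apply_percent_threshold(p, pct)) for p in profiles],
                dtype=float,
            )
            if np.all(counts == counts[0]):
                p_one = 1.0
            else:
                p_one = stats.pearsonr(counts, totals, alternative="greater")[1]
            if p_one >= 0.05:
                assert chosen == pct
                break
        counts = np.array(
            [len(apply_percent_threshold(p, chosen)) for p in profiles],
            dtype=float,
        )
        if not np.all(counts == counts[0]):
            r = stats.pearsonr(counts, totals)[0]
            assert r < 0.3


def interval_oracle(profiles, params, offset):
    """Direct interval-arithmetic binning used to check bin_frames."""
    start = params.size_min + offset
    retained = 0.0
    membership = {}
    for si, prof in enumerate(profiles):
        total = prof.total_fluorescence
        for size, area in prof.peaks:
            k = int(np.floor((size - start) / params.window_ws))
            if k < 0:
                continue
            retained += area / total if total else 0.0
            membership.setdefault((si, k), 0.0)
            membership[(si, k)] += area / total
    return retained, membership


class TestBinning:
    params = BinningParams()

    def test_ws1_sh01_gives_ten_frames(self):
        profiles = [consensus([(100.0, 1.0)])]
        frames = bin_frames(profiles, self.params)
        assert len(frames) == 10
        assert [round(f.frame_offset, 1) for f in frames] == [
            round(0.1 * j, 1) for j in range(10)
        ]

    def test_shared_exact_peak_single_bin_every_frame(self):
        profiles = [
            consensus([(100.0, 5.0)], sample=f"S{j}") for j in range(4)
        ]
        for frame in bin_frames(profiles, self.params):
            assert len(frame.bin_centers) == 1
            assert frame.bin_centers[0] == pytest.approx(100.0)
            assert np.allclose(frame.values, 1.0)

    def test_close_peaks_join_or_split_per_interval_oracle(self):
        profiles = [
            consensus([(100.45, 1.0)], sample="S0"),
            consensus([(100.55, 1.0)], sample="S1"),
        ]
        for frame in bin_frames(profiles, self.params):
            _, membership = interval_oracle(profiles, self.params, frame.frame_offset)
            oracle_bins = {k for _, k in membership}
            assert len(frame.bin_centers) == len(oracle_bins)

    def test_mixed_enzyme_profiles_rejected(self):
        with pytest.raises(ValueError, match="enzyme"):
            bin_frames(
                [consensus([(100, 1)]), consensus([(100, 1)], enzyme="MspI")],
                self.params,
            )

    def test_best_frame_matches_exhaustive_scores(self, rng):
        for _ in range(25):
            n_samples = int(rng.integers(2, 6))
            profiles = [
                consensus(
                    [
                        (float(rng.uniform(81, 599)), float(rng.uniform(1, 100)))
                        for _ in range(int(rng.integers(1, 7)))
                    ],
                    sample=f"S{j}",
                )
                for j in range(n_samples)
            ]
            frames = bin_frames(profiles, self.params)
            best = select_best_frame(frames)
            oracle_scores = [
                interval_oracle(profiles, self.params, f.frame_offset)[0]
                for f in frames
            ]
            assert best.score == pytest.approx(max(oracle_scores))

    def test_tie_broken_by_smaller_offset(self):
        a = BinnedMatrix("CfoI", ("S0",), (100.0,), np.array([[1.0]]), 0.4)
        b = BinnedMatrix("CfoI", ("S0",), (100.0,), np.array([[1.0]]), 0.2)
        assert select_best_frame([a, b]).frame_offset == 0.2
        assert select_best_frame([b, a]).frame_offset == 0.2

    def test_presence_absence(self):
        m = BinnedMatrix(
            "CfoI", ("S0", "S1"), (100.0, 200.0),
            np.array([[0.371, 0.0], [0.0, 0.0]]), 0.0,
        )
        assert to_presence_absence(m).tolist() == [[1, 0], [0, 0]]


class TestPipeline:
    def test_noise_free_profiles_recover_planted_trfs(self):
        config = ScenarioConfig(seed=5, jitter_sd=0.0, background_peak_rate=0.0)
        taxa = simulate_taxa(config)
        records = simulate_peak_tables(taxa, config)
        profiler = TRFLPProfiler(enzyme="CfoI", pct=1.2).fit(records)
        planted = {t.true_trf["CfoI"] for t in taxa}
        observed = {round(c) for c in profiler.matrix_.bin_centers}
        assert observed <= planted
        # every bin center sits exactly on a planted integer TRF
        for c in profiler.matrix_.bin_centers:
            assert c == pytest.approx(round(c))

    def test_best_frame_rows_sum_to_one(self, default_config):
        taxa = simulate_taxa(default_config)
        records = simulate_peak_tables(taxa, default_config)
        profiler = TRFLPProfiler(enzyme="CfoI").fit(records)
        sums = profiler.matrix_.values.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_best_frame_keeps_planted_trfs_single_binned(self):
        # size-call jitter below the bin width must not split a TRF
        hits = 0
        trials = 20
        for seed in range(trials):
            config = ScenarioConfig(seed=seed)
            taxa = simulate_taxa(config)
            records = simulate_peak_tables(taxa, config)
            profiler = TRFLPProfiler(enzyme="CfoI").fit(records)
            centers = np.array(profiler.matrix_.bin_centers)
            planted = [t.true_trf["CfoI"] for t in taxa]
            ok = all(
                (np.abs(centers - trf) < 0.5).sum() <= 1 for trf in planted
            )
            hits += ok
        assert hits >= trials - 1

    def test_missing_replicate_is_error(self):
        from trflpkit.io import PeakRecord

        records = [PeakRecord("A", "x", "y", 1, "CfoI", 100.0, 10.0)]
        with pytest.raises(ValueError, match="replicate"):
            profiles_from_records(records, "CfoI")

    def test_profiler_is_sklearn_compatible(self):
        from sklearn.base import clone

        est = TRFLPProfiler(enzyme="MspI", pct=1.2)
        cloned = clone(est)
        assert cloned.get_params()["enzyme"] == "MspI"
        cloned.set_params(pct="auto")
        assert cloned.pct == "auto"
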