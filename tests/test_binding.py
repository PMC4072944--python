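import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from paralogbind import binding, synthetic
from paralogbind.binding import (
    NoThresholdError,
    SignalProfile,
    WindowScore,
    call_intervals,
    core_intersect,
    estimate_fdr_threshold,
    quantile_normalize,
    smooth_windows,
)
from paralogbind.evaluate import binding_call_fdp

from conftest import make_layout


class TestQuantileNormalize:
    def test_hand_computed_mean_of_order_statistics(self):
        m = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        out = quantile_normalize(np.column_stack([col, col, col]))
        np.testing.assert_allclose(out, np.column_stack([col, col, col]))

    def test_sorted_columns_identical_and_ranks_preserved(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(200, 4))
        out = quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
            assert (rankdata(out[:, j]) == rankdata(m[:, j])).all()

    def test_pooled_mean_conserved(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(500, 3))
        out = quantile_normalize(m)
        assert np.isclose(out.mean(), m.mean(), atol=1e-9)

    def test_constant_column_maps_into_reference(self):
        m = np.column_stack([np.full(5, 7.0), np.arange(5, dtype=float)])
        out = quantile_normalize(m)
        # constant column: all ranks tied at the middle of the reference
        assert np.allclose(out[:, 0], out[:, 0][0])


class TestSmoothWindows:
    def test_constant_profile_unchanged(self):
        layout = make_layout(20)
        prof = SignalProfile(layout, np.full((20, 3), 2.5))
        ws = smooth_windows(prof, half_width=250, min_probes=3)
        np.testing.assert_allclose(ws.scores, 2.5)

    def test_single_probe_spike_removed_by_median(self):
        layout = make_layout(9)
        v = np.zeros((9, 1))
        v[4, 0] = 10.0
        ws = smooth_windows(SignalProfile(layout, v), half_width=150, min_probes=3)
        assert ws.scores[4] == 0.0  # median of (0, 10, 0)

    def test_insufficient_coverage_is_undefined(self):
        layout = make_layout(1)
        ws = smooth_windows(
            SignalProfile(layout, np.ones((1, 1))), half_width=100, min_probes=3
        )
        assert np.isnan(ws.scores[0])

    def test_nonpositive_half_width_rejected(self):
        layout = make_layout(3)
        with pytest.raises(ValueError):
            smooth_windows(SignalProfile(layout, np.ones((3, 1))), half_width=0)


def brute_force_runs(starts, ends, above, threshold_scores, min_probes, max_gap):
    """Exhaustive run enumeration on one chromosome."""
    runs, run = [], []
    for i, ok in enumerate(above):
        if not ok:
            continue
        if run and starts[i] - ends[run[-1]] > max_gap:
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)
    return [
        (int(starts[r[0]]), int(ends[r[-1]]), len(r))
        for r in runs
        if len(r) >= min_probes
    ]


class TestCallIntervals:
    def test_basic_run(self):
        layout = make_layout(5)
        ws = WindowScore(layout, np.array([0, 2, 2, 2, 0.0]), 250, 3)
        calls = call_intervals(ws, threshold=1.0, min_probes=3, max_gap=200)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["start"] == 100 and row["end"] == 350 and row["n_probes"] == 3

    def test_gap_larger_than_max_gap_splits(self):
        layout = make_layout(10, spacing=300)  # inter-probe gap 250 > 200
        scores = np.full(10, 5.0)
        calls = call_intervals(WindowScore(layout, scores, 250, 3), 1.0, 1, max_gap=200)
        assert len(calls) == 10
        calls2 = call_intervals(WindowScore(layout, scores, 250, 3), 1.0, 1, max_gap=300)
        assert len(calls2) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        layout = make_layout(n, spacing=int(rng.integers(60, 200)))
        scores = rng.normal(size=n)
        scores[rng.random(n) < 0.1] = np.nan
        t = float(rng.normal(scale=0.5))
        min_probes = int(rng.integers(1, 5))
        max_gap = int(rng.integers(50, 400))
        calls = call_intervals(WindowScore(layout, scores, 250, 3), t, min_probes, max_gap)
        above = np.nan_to_num(scores, nan=-np.inf) >= t
        expected = brute_force_runs(
            layout["start"].to_numpy(), layout["end"].to_numpy(), above, scores,
            min_probes, max_gap,
        )
        got = list(zip(calls["start"], calls["end"], calls["n_probes"]))
        assert got == expected

    def test_intervals_never_overlap(self):
        rng = np.random.default_rng(3)
        layout = make_layout(300)
        scores = rng.normal(size=300)
        calls = call_intervals(WindowScore(layout, scores, 250, 3), 0.0, 2, 200)
        assert (calls["start"].to_numpy()[1:] >= calls["end"].to_numpy()[:-1]).all()


class TestFdrThreshold:
    def _window(self, genome, probes, truth, noise_sd, seed):
        profiles = synthetic.simulate_binding_profiles(
            genome, probes, truth, noise_sd=noise_sd, n_replicates=3, seed=seed
        )
        prof = profiles["A_wt"]
        qn = quantile_normalize(prof.values)
        return smooth_windows(SignalProfile(prof.layout, qn), 250, 3)

    def test_all_zero_scores_raise(self):
        layout = make_layout(50)
        ws = WindowScore(layout, np.zeros(50), 250, 3)
        with pytest.raises(NoThresholdError):
            estimate_fdr_threshold(ws, 0.05)

    def test_invalid_target_rejected(self):
        layout = make_layout(10)
        ws = WindowScore(layout, np.ones(10), 250, 3)
        with pytest.raises(ValueError):
            estimate_fdr_threshold(ws, 1.5)

    def test_planted_plateaus_recovered(self, small_genome, probes):
        genome, _ = small_genome
        truth = synthetic.plant_binding_events(genome, n_per_event=4, seed=7)
        ws = self._window(genome, probes, truth, noise_sd=0.3, seed=1)
        t = estimate_fdr_threshold(ws, 0.05)
        # null window scores are medians of ~5 probes of replicate-mean noise
        # (sd ~0.3/sqrt(3) * 0.54); threshold must clear that scale yet stay
        # below the planted plateau
        null_scale = 0.3 / np.sqrt(3) * 0.54
        assert null_scale < t < 3.0
        calls = call_intervals(ws, t, 3, 200)
        fdp = binding_call_fdp(calls, truth)
        assert fdp <= 0.10
        # every planted wild-type A region is hit
        planted = truth.planted_binding.query("factor=='A' and condition=='wt'")
        for r in planted.itertuples(index=False):
            assert (
                (calls["chrom"] == r.chrom)
                & (calls["start"] < r.end)
                & (r.start < calls["end"])
            ).any()

    def test_interval_counts_nondecreasing_in_fdr(self, small_genome, probes):
        genome, _ = small_genome
        truth = synthetic.plant_binding_events(genome, n_per_event=4, seed=8)
        ws = self._window(genome, probes, truth, noise_sd=0.4, seed=2)
        counts = [
            len(call_intervals(ws, estimate_fdr_threshold(ws, f), 3, 200))
            for f in (0.01, 0.05, 0.10, 0.25)
        ]
        assert counts == sorted(counts)


class TestCoreIntersect:
    def test_overlap_retained_with_support_label(self):
        ref = {"dam": pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])}
        sup = {"chip": pd.DataFrame([{"chrom": "chr1", "start": 150, "end": 250}])}
        core = core_intersect(ref, sup)
        assert len(core) == 1
        assert core.iloc[0]["support"] == "chip"
        assert core.iloc[0]["start"] == 100 and core.iloc[0]["end"] == 200

    def test_half_open_touching_intervals_do_not_overlap(self):
        ref = {"dam": pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])}
        sup = {"chip": pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 300}])}
        assert len(core_intersect(ref, sup)) == 0

    def test_empty_reference_warns(self):
        ref = {"dam": pd.DataFrame(columns=["chrom", "start", "end"])}
        sup = {"chip": pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10}])}
        with pytest.warns(UserWarning):
            core = core_intersect(ref, sup)
        assert len(core) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_set(n):
            starts = rng.integers(0, 5000, size=n)
            return pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], size=n),
                    "start": starts,
                    "end": starts + rng.integers(10, 400, size=n),
                }
            )

        ref = {"r": random_set(40)}
        sup = {"s1": random_set(30), "s2": random_set(30)}
        core = core_intersect(ref, sup)
        expected = 0
        for a in ref["r"].itertuples(index=False):
            hit = any(
                a.chrom == b.chrom and a.start < b.end and b.start < a.end
                for s in sup.values()
                for b in s.itertuples(index=False)
            )
            expected += hit
        assert len(core) == expected
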