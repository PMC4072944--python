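import itertools

import numpy as np
import pandas as pd
import pytest

from paralogbind.annotation import (
    PWM,
    GeneModel,
    assign_interval_to_gene,
    assign_intervals,
    classify_features,
    classify_midpoint_feature,
    estimate_background,
    profile_signal_around,
    pwm_scan,
    reverse_complement,
    tss_position_stats,
)

from conftest import make_gene


class TestAssignment:
    def test_tss_within_window_wins(self):
        genes = [make_gene("g1", "chr1", "+", 10_000, 15_000)]
        a = assign_interval_to_gene(("chr1", 4_800, 5_200), genes)
        assert a.rule == "tss" and a.gene_id == "g1" and a.distance == 5_000

    def test_boundary_fallback_when_no_tss_in_window(self):
        # minus-strand gene: TSS at the right end, 18 kb from the midpoint,
        # but the gene start boundary is 8 kb away
        genes = [make_gene("g1", "chr1", "-", 13_000, 23_000)]
        a = assign_interval_to_gene(("chr1", 4_800, 5_200), genes)
        assert a.rule == "boundary" and a.gene_id == "g1" and a.distance == 8_000

    def test_everything_beyond_window_unassigned(self):
        genes = [make_gene("g1", "chr1", "+", 16_000, 17_000)]
        a = assign_interval_to_gene(("chr1", 4_800, 5_200), genes)
        assert a.rule == "unassigned" and a.gene_id is None

    def test_unknown_chromosome_unassigned(self):
        genes = [make_gene("g1", "chr1", "+", 0, 1_000)]
        a = assign_interval_to_gene(("chr9", 100, 200), genes)
        assert a.rule == "unassigned"

    def test_tie_breaks_to_smaller_gene_id(self):
        genes = [
            make_gene("gB", "chr1", "+", 6_000, 7_000),
            make_gene("gA", "chr1", "-", 3_000, 4_001),  # TSS at 4000
        ]
        # midpoint 5000: both TSSs at distance 1000
        a = assign_interval_to_gene(("chr1", 4_900, 5_100), genes)
        assert a.gene_id == "gA"

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        window = 10_000
        for _ in range(200):
            genes = [
                make_gene(
                    f"g{i}", "chr1", rng.choice(["+", "-"]),
                    int(s := rng.integers(0, 90_000)), int(s + rng.integers(500, 8_000)),
                )
                for i in range(rng.integers(1, 8))
            ]
            start = int(rng.integers(0, 99_000))
            interval = ("chr1", start, start + 1_000)
            mid = start + 500
            # oracle: exhaustive nearest-feature search
            tss_c = sorted(
                ((abs(mid - g.tss), g.gene_id) for g in genes if abs(mid - g.tss) <= window)
            )
            bnd_c = sorted(
                (
                    (min(abs(mid - g.start), abs(mid - (g.end - 1))), g.gene_id)
                    for g in genes
                    if min(abs(mid - g.start), abs(mid - (g.end - 1))) <= window
                )
            )
            a = assign_interval_to_gene(interval, genes, window)
            if tss_c:
                assert (a.rule, a.distance, a.gene_id) == ("tss", tss_c[0][0], tss_c[0][1])
            elif bnd_c:
                assert (a.rule, a.distance, a.gene_id) == (
                    "boundary", bnd_c[0][0], bnd_c[0][1]
                )
            else:
                assert a.rule == "unassigned"


class TestFeatures:
    def _gene_with_structure(self):
        return GeneModel(
            "g1", "chr1", "+", 1_000, 10_000,
            exons=[(1_000, 3_000), (6_000, 10_000)],
            utrs=[(1_000, 1_500), (9_500, 10_000)],
        )

    def test_intron_exon_utr_intergenic(self):
        g = self._gene_with_structure()
        assert classify_midpoint_feature(("chr1", 3_900, 4_100), [g]) == "intron"
        assert classify_midpoint_feature(("chr1", 1_900, 2_100), [g]) == "exon"
        assert classify_midpoint_feature(("chr1", 1_100, 1_300), [g]) == "UTR"
        assert classify_midpoint_feature(("chr1", 20_000, 20_100), [g]) == "intergenic"

    def test_mixed_when_genes_disagree(self):
        g1 = self._gene_with_structure()
        g2 = GeneModel("g2", "chr1", "-", 1_500, 5_000, exons=[(3_500, 5_000)])
        # midpoint 4000: intron of g1, exon of g2
        assert classify_midpoint_feature(("chr1", 3_900, 4_100), [g1, g2]) == "mixed"
        # agreeing features are not mixed
        g3 = GeneModel("g3", "chr1", "-", 1_500, 5_000, exons=[(1_500, 2_000)])
        assert classify_midpoint_feature(("chr1", 3_900, 4_100), [g1, g3]) == "intron"

    def test_feature_classes_partition_interval_set(self):
        rng = np.random.default_rng(1)
        genes = [self._gene_with_structure()]
        starts = rng.integers(0, 30_000, size=50)
        intervals = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 200}
        )
        features = classify_features(intervals, genes)
        assert features.value_counts().sum() == len(intervals)


class TestTssStats:
    def test_all_upstream_on_plus_strand(self):
        genes = [make_gene("g1", "chr1", "+", 10_000, 12_000)]
        intervals = pd.DataFrame(
            {"chrom": "chr1", "start": [4_000, 6_000, 8_000], "end": [4_200, 6_200, 8_200]}
        )
        stats = tss_position_stats(assign_intervals(intervals, genes), genes)
        assert stats["upstream_fraction"] == 1.0

    def test_minus_strand_reflection(self):
        # minus-strand TSS at 999 within [0, 1000); midpoint 1200 lies 5' of
        # the TSS in reading direction -> upstream
        genes = [make_gene("g1", "chr1", "-", 0, 1_000)]
        intervals = pd.DataFrame({"chrom": "chr1", "start": [1_100], "end": [1_300]})
        stats = tss_position_stats(assign_intervals(intervals, genes), genes)
        assert stats["upstream_fraction"] == 1.0

    def test_symmetric_placement_near_half(self):
        rng = np.random.default_rng(2)
        genes = [make_gene("g1", "chr1", "+", 50_000, 60_000)]
        n = 400
        offsets = rng.integers(-9_000, 9_000, size=n)
        intervals = pd.DataFrame(
            {"chrom": "chr1", "start": 50_000 + offsets - 100, "end": 50_000 + offsets + 100}
        )
        stats = tss_position_stats(assign_intervals(intervals, genes), genes)
        se = np.sqrt(0.25 / n)
        assert abs(stats["upstream_fraction"] - 0.5) < 4 * se


class TestProfileSignal:
    def test_constant_track_flat_profile(self):
        track = {"chr1": np.full(50_000, 3.0)}
        intervals = pd.DataFrame({"chrom": "chr1", "start": [25_000], "end": [25_200]})
        prof = profile_signal_around(intervals, track, flank=5_000, n_bins=11)
        np.testing.assert_allclose(prof["mean_score"], 3.0)

    def test_planted_central_peak(self):
        track = {"chr1": np.zeros(50_000)}
        track["chr1"][24_800:25_400] = 1.0  # high patch at interval centres
        intervals = pd.DataFrame({"chrom": "chr1", "start": [25_000], "end": [25_200]})
        prof = profile_signal_around(intervals, track, flank=5_000, n_bins=11)
        assert prof["mean_score"].idxmax() == 5  # central bin

    def test_interval_near_chromosome_start_truncates(self):
        track = {"chr1": np.ones(2_000)}
        intervals = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [300]})
        prof = profile_signal_around(intervals, track, flank=5_000, n_bins=11)
        assert prof["n_bases"].iloc[0] == 0 and np.isnan(prof["mean_score"].iloc[0])
        assert prof["mean_score"].iloc[5] == 1.0

    def test_no_intervals_rejected(self):
        with pytest.raises(ValueError):
            profile_signal_around(
                pd.DataFrame(columns=["chrom", "start", "end"]), {"chr1": np.ones(10)}
            )


def consensus_pwm(consensus: str, certainty: float = 0.997) -> PWM:
    rows = []
    for b in consensus:
        row = np.full(4, (1 - certainty) / 3)
        row["ACGT".index(b)] = certainty
        rows.append(row)
    return PWM(np.array(rows), background=np.full(4, 0.25), p_threshold=1e-4)


class TestPwmScan:
    def test_strict_consensus_matches_string_search(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        # width 8 so an exact-match p-value (4^-8) clears the 1e-4 cutoff;
        # a 6-mer consensus cannot reach it under a uniform background
        motif = "ATTGTTAC"
        pwm = consensus_pwm(motif)
        hits = pwm_scan({"chr1": seq}, pwm, background=np.full(4, 0.25))
        expected = set()
        rc = reverse_complement(motif)
        for i in range(len(seq) - len(motif) + 1):
            word = seq[i : i + len(motif)]
            if word == motif:
                expected.add((i, "+"))
            if word == rc:
                expected.add((i, "-"))
        got = set(zip(hits["start"], hits["strand"]))
        assert got == expected

    def test_p_threshold_one_reports_every_window(self):
        seq = "ACGTACGTACGT"
        pwm = consensus_pwm("ACGT")
        pwm.p_threshold = 1.0
        hits = pwm_scan({"chr1": seq}, pwm, background=np.full(4, 0.25))
        assert len(hits) == 2 * (len(seq) - 4 + 1)

    def test_windows_with_n_skipped(self):
        pwm = consensus_pwm("ACGT")
        pwm.p_threshold = 1.0
        hits = pwm_scan({"chr1": "ACNTACGT"}, pwm, background=np.full(4, 0.25))
        assert (hits["start"] >= 3).all() or len(hits) == 0

    def test_dp_pvalues_match_exhaustive_enumeration(self):
        """For width <= 8, the DP survival function equals brute-force
        enumeration over all 4^w background words."""
        rng = np.random.default_rng(4)
        w = 5
        probs = rng.dirichlet(np.ones(4) * 2, size=w)
        pwm = PWM(probs, background=np.full(4, 0.25), p_threshold=1.0)
        bg = np.full(4, 0.25)
        lom = pwm.log_odds(bg)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = pwm_scan({"chr1": seq}, pwm, background=bg)
        # exhaustive null distribution
        word_scores = np.array(
            [
                lom[np.arange(w), list(word)].sum()
                for word in itertools.product(range(4), repeat=w)
            ]
        )
        for _, hit in hits.head(40).iterrows():
            exact = (word_scores >= hit["score"] - 1e-9).mean()
            assert np.isclose(hit["p_value"], exact, rtol=0.05, atol=1e-4)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1_500))
        pwm = consensus_pwm("TTGTTA")
        pwm.p_threshold = 1e-3
        fwd = pwm_scan({"chr1": seq}, pwm, background=np.full(4, 0.25))
        rev = pwm_scan({"chr1": reverse_complement(seq)}, pwm, background=np.full(4, 0.25))
        L = len(seq)
        reflected = {
            (L - r.end, L - r.start, {"+": "-", "-": "+"}[r.strand])
            for r in rev.itertuples(index=False)
        }
        original = {(r.start, r.end, r.strand) for r in fwd.itertuples(index=False)}
        assert original == reflected

    def test_pwm_wider_than_sequence_empty(self):
        pwm = consensus_pwm("ACGTACGTA")
        assert len(pwm_scan({"chr1": "ACGT"}, pwm, background=np.full(4, 0.25))) == 0

    def test_background_estimation_strand_symmetric(self):
        bg = estimate_background({"chr1": "AAAACCC"})
        assert np.isclose(bg.sum(), 1.0)
        assert np.isclose(bg[0], bg[3]) and np.isclose(bg[1], bg[2])

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError):
            PWM(np.full((3, 4), 0.25))  # width < 4
        with pytest.raises(ValueError):
            PWM(np.full((6, 4), 0.25), background=np.array([0.5, 0.5, 0.5, 0.5]))
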