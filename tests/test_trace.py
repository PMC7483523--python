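"""Trace container, rebinning, burst detection and Poisson masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pscfcs import trace as tr
from pscfcs.exceptions import DegenerateInputError, InvalidArgumentError


def make_trace(donor, acceptor, bin_width=1e-3):
    return tr.BinnedTrace(bin_width=bin_width, donor=np.asarray(donor),
                          acceptor=np.asarray(acceptor))


class TestBinnedTrace:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            make_trace([1, 2], [1, 2, 3])
        with pytest.raises(InvalidArgumentError):
            make_trace([1, -2], [1, 2])
        with pytest.raises(InvalidArgumentError):
            tr.BinnedTrace(bin_width=0.0, donor=np.array([1]), acceptor=np.array([1]))
        with pytest.raises(InvalidArgumentError):
            make_trace([1.5], [1])

    def test_duration_and_sum(self):
        t = make_trace([1, 2, 3], [0, 1, 0], bin_width=0.5)
        assert t.duration == pytest.approx(1.5)
        assert t.channel_sum().tolist() == [1, 3, 3]


class TestRebin:
    def test_identity_and_pairwise(self):
        t = make_trace([1, 2, 3, 4], [0, 0, 1, 1])
        assert tr.rebin(t, 1) is t
        r = tr.rebin(t, 2)
        assert r.donor.tolist() == [3, 7]
        assert r.acceptor.tolist() == [0, 2]
        assert r.bin_width == pytest.approx(2e-3)

    def test_invalid_factor(self):
        t = make_trace([1, 2], [0, 0])
        with pytest.raises(InvalidArgumentError):
            tr.rebin(t, 0)
        with pytest.raises(InvalidArgumentError):
            tr.rebin(t, 2.5)

    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=60),
        factor=st.integers(1, 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, counts, factor):
        """Total counts are conserved up to the dropped remainder."""
        if len(counts) < factor:
            return
        t = make_trace(counts, [0] * len(counts))
        r = tr.rebin(t, factor)
        kept = (len(counts) // factor) * factor
        assert r.donor.sum() == sum(counts[:kept])


class TestDetectBursts:
    def test_empty_and_all_zero(self):
        assert tr.detect_bursts(make_trace([], []), 1) == []
        assert tr.detect_bursts(make_trace([0, 0, 0], [0, 0, 0]), 1) == []

    def test_single_bin_burst_efficiency(self):
        t = make_trace([0, 30, 0], [0, 70, 0])
        bursts = tr.detect_bursts(t, 50)
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.start_bin, b.end_bin) == (1, 2)
        assert b.e_app == pytest.approx(0.70)

    def test_maximal_runs_and_sums(self):
        t = make_trace([5, 5, 0, 5, 0], [0, 1, 0, 0, 0])
        bursts = tr.detect_bursts(t, 5)
        assert [(b.start_bin, b.end_bin) for b in bursts] == [(0, 2), (3, 4)]
        assert bursts[0].donor_sum == 10 and bursts[0].acceptor_sum == 1

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, counts):
        """Raising the threshold never creates a burst bin absent at a
        lower threshold, and burst/background bins partition the trace."""
        t = make_trace(counts, [0] * len(counts))

        def burst_bins(thr):
            bins = set()
            for b in tr.detect_bursts(t, thr):
                bins.update(range(b.start_bin, b.end_bin))
            return bins

        low, high = burst_bins(3), burst_bins(7)
        assert high <= low
        # partition: every bin is exactly burst or background
        bursts = tr.detect_bursts(t, 5)
        mask = tr._background_mask(len(t), bursts)
        assert mask.sum() + len(burst_bins(5)) == len(t)

    def test_ground_truth_transits_are_detected(self, single_species_sim):
        """Transit windows whose peak expected intensity clears the
        threshold should overlap detected bursts (>= 90%)."""
        trace, log, cfg = single_species_sim
        coarse = tr.rebin(trace, cfg.gt_factor)
        threshold = 8.0
        bursts = tr.detect_bursts(coarse, threshold)
        burst_bins = np.zeros(len(coarse), dtype=bool)
        for b in bursts:
            burst_bins[b.start_bin : b.end_bin] = True
        total = hit = 0
        for mol in range(log.n_molecules):
            for s, e in log.transit_windows(mol):
                if log.window_peak_intensity(mol, (s, e)) < 2 * threshold:
                    continue
                total += 1
                if burst_bins[s : min(e, len(coarse))].any():
                    hit += 1
        assert total > 20
        assert hit / total >= 0.9


class TestBackground:
    def test_all_zero_and_constant(self):
        t = make_trace([0, 0, 0], [0, 0, 0])
        bg = tr.estimate_background(t, [])
        assert (bg.donor_rate, bg.acceptor_rate) == (0.0, 0.0)
        t2 = make_trace([2, 2, 2, 2], [1, 1, 1, 1])
        bg2 = tr.estimate_background(t2, [])
        assert bg2.donor_rate == pytest.approx(2.0)
        assert bg2.acceptor_rate == pytest.approx(1.0)

    def test_burst_bins_excluded(self):
        t = make_trace([1, 100, 1, 1], [0, 50, 0, 0])
        bursts = tr.detect_bursts(t, 50)
        bg = tr.estimate_background(t, bursts)
        assert bg.donor_rate == pytest.approx(1.0)

    def test_no_background_bins_is_degenerate(self):
        t = make_trace([9, 9], [0, 0])
        bursts = tr.detect_bursts(t, 1)
        with pytest.raises(DegenerateInputError):
            tr.estimate_background(t, bursts)

    def test_poisson_rate_recovery(self, rng):
        """Estimated rate lies within 3 standard errors of the true
        Poisson rate on a long background-only trace."""
        lam, n = 0.05, 1_000_000
        t = make_trace(rng.poisson(lam, n), rng.poisson(lam, n))
        bg = tr.estimate_background(t, [])
        se = np.sqrt(lam / n)
        assert abs(bg.donor_rate - lam) < 3 * se
        assert abs(bg.acceptor_rate - lam) < 3 * se


class TestPoissonMasking:
    def test_keep_everything_is_identity(self):
        t = make_trace([1, 5, 2, 8], [0, 3, 1, 2])
        out = tr.poisson_masked_trace(t, [(0, 4)], tr.BackgroundModel(1, 1), seed=1)
        assert out.donor.tolist() == t.donor.tolist()
        assert out.acceptor.tolist() == t.acceptor.tolist()

    def test_keep_nothing_zero_background(self):
        t = make_trace([1, 5, 2, 8], [0, 3, 1, 2])
        out = tr.poisson_masked_trace(t, [], tr.BackgroundModel(0, 0), seed=1)
        assert out.channel_sum().sum() == 0

    def test_replacement_statistics(self):
        """Replaced bins follow the requested Poisson law (mean within
        3 standard errors)."""
        n, lam = 100_000, 1.0
        t = make_trace(np.zeros(n, int), np.zeros(n, int))
        out = tr.poisson_masked_trace(t, [], tr.BackgroundModel(lam, 0), seed=3)
        assert abs(out.donor.mean() - lam) < 3 * np.sqrt(lam / n)

    def test_kept_windows_bit_exact_and_reproducible(self, rng):
        t = make_trace(rng.poisson(2, 500), rng.poisson(2, 500))
        keep = [(100, 150), (300, 320)]
        a = tr.poisson_masked_trace(t, keep, tr.BackgroundModel(0.5, 0.5), seed=9)
        b = tr.poisson_masked_trace(t, keep, tr.BackgroundModel(0.5, 0.5), seed=9)
        assert np.array_equal(a.donor, b.donor) and np.array_equal(a.acceptor, b.acceptor)
        for s, e in keep:
            assert np.array_equal(a.donor[s:e], t.donor[s:e])

    def test_overlapping_windows_rejected(self):
        t = make_trace([1] * 10, [0] * 10)
        with pytest.raises(InvalidArgumentError):
            tr.poisson_masked_trace(t, [(0, 5), (4, 8)], tr.BackgroundModel(1, 1), 0)


class TestWindowMapping:
    def test_coarse_to_fine_merging(self):
        bursts = [
            tr.Burst(0, 2, 1, 1, 0.5),
            tr.Burst(2, 3, 1, 1, 0.5),  # adjacent: merges
            tr.Burst(5, 6, 1, 1, 0.5),
        ]
        windows = tr.burst_windows_to_fine(bursts, factor=10, n_fine=55)
        assert windows == [(0, 30), (50, 55)]


class TestEfficiencyCorrection:
    def test_background_subtraction(self):
        b = tr.Burst(0, 2, donor_sum=20, acceptor_sum=10, e_app=10 / 30)
        [c] = tr.background_corrected_efficiency([b], tr.BackgroundModel(5, 4))
        # corrected: donor 20-10=10, acceptor 10-8=2
        assert c.e_app == pytest.approx(2 / 12)

    def test_donor_only_can_go_negative(self):
        b = tr.Burst(0, 1, donor_sum=50, acceptor_sum=1, e_app=1 / 51)
        [c] = tr.background_corrected_efficiency([b], tr.BackgroundModel(0, 2))
        assert c.e_app < 0


class TestTraceIO:
    @pytest.mark.parametrize("ext", ["h5", "tsv"])
    def test_round_trip(self, tmp_path, rng, ext):
        t = make_trace(rng.poisson(2, 40), rng.poisson(1, 40), bin_width=0.96e-6)
        path = tmp_path / f"trace.{ext}"
        tr.write_trace(path, t)
        back = tr.read_trace(path)
        assert back.bin_width == pytest.approx(t.bin_width)
        assert np.array_equal(back.donor, t.donor)
        assert np.array_equal(back.acceptor, t.acceptor)

    def test_burst_table(self):
        bursts = tr.detect_bursts(make_trace([0, 9, 0], [0, 1, 0]), 5)
        table = tr.bursts_to_table(bursts)
        assert list(table.columns) == [
            "start_bin", "end_bin", "donor_sum", "acceptor_sum", "e_app",
        ]
        assert table.iloc[0]["donor_sum"] == 9
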