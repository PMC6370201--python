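import numpy as np
import pytest

from dyadsync import (
    AnalysisConfig,
    R2Landscape,
    SmoothingSpec,
    SyncIntervalRecord,
    TransformSpec,
    ZeroVarianceError,
    compute_landscape,
    filter_by_cutoff,
    identify_msi,
    peak_pick,
    window_association_wclc,
    window_association_wclr,
)
from dyadsync.detection import MIN_MSI_FRAMES
from dyadsync.synthetic_data import DyadSequence, IntervalSpec
from dyadsync.motion_energy import MotionEnergySeries


class TestWindowAssociationWCLC:
    def test_perfect_copy(self, rng):
        a = rng.normal(0, 1, 50)
        r2, p = window_association_wclc(a, a.copy())
        assert r2 == pytest.approx(1.0)
        assert p < 1e-12

    def test_sign_blind(self, rng):
        a = rng.normal(0, 1, 50)
        r2, _ = window_association_wclc(a, -a)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        r2, _ = window_association_wclc(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0]))
        assert r2 == pytest.approx(0.64)  # Pearson r = 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            window_association_wclc(np.full(10, 2.0), np.arange(10.0))


class TestWindowAssociationWCLR:
    def test_echoed_white_noise_explains_almost_everything(self, rng):
        """White noise has no AR structure, so an exact copy as predictor
        captures nearly all variance beyond the autoregressive baseline."""
        a = rng.normal(0, 1, 125)
        delta, p = window_association_wclr(a, a.copy())
        assert delta > 0.9
        assert p < 1e-3

    def test_independent_ar1_near_null(self, rng):
        """Monte-Carlo null: independent AR(1) windows give small mean
        delta-R2, cross-checked against a direct least-squares solve."""
        deltas = []
        direct = []
        for _ in range(1000):
            a = np.empty(40)
            b = np.empty(40)
            a[0] = rng.normal()
            b[0] = rng.normal()
            for i in range(1, 40):
                a[i] = 0.6 * a[i - 1] + rng.normal()
                b[i] = 0.6 * b[i - 1] + rng.normal()
            delta, _ = window_association_wclr(a, b)
            deltas.append(delta)
            # oracle: explicit OLS of both nested models
            y, x1, x2 = b[1:], b[:-1], a[1:]
            X0 = np.column_stack([np.ones_like(x1), x1])
            X1 = np.column_stack([np.ones_like(x1), x1, x2])
            tss = np.sum((y - y.mean()) ** 2)
            r0 = 1 - np.sum(np.linalg.lstsq(X0, y, rcond=None)[1]) / tss
            r1 = 1 - np.sum(np.linalg.lstsq(X1, y, rcond=None)[1]) / tss
            direct.append(r1 - r0)
        assert np.mean(deltas) < 0.05
        np.testing.assert_allclose(deltas, direct, atol=1e-10)

    def test_constant_window_rejected(self):
        with pytest.raises(ZeroVarianceError):
            window_association_wclr(np.full(20, 1.0), np.arange(20.0))


def _noise_config(**kw):
    defaults = dict(
        method="WCLC",
        transform=TransformSpec("raw"),
        smoothing=SmoothingSpec("none"),
        bandwidth=125,
        r2_cutoff=0.25,
    )
    defaults.update(kw)
    return AnalysisConfig(**defaults)


class TestComputeLandscape:
    def test_exact_echo_peaks_at_construction_lag(self, rng):
        """B = A shifted by +50 frames, noiseless non-degenerate series:
        every fully-overlapping window has r2 = 1 at lag 50."""
        n = 600
        a = rng.gamma(2.0, 2.0, n) + 0.1 * rng.normal(0, 1, n)
        b = np.zeros(n)
        b[50:] = a[:-50]
        cfg = _noise_config(bandwidth=125)
        # windows touching the zero-padded head of b are skipped at some lags
        landscape = compute_landscape(a, b, cfg)
        j50 = int(np.where(landscape.lag_grid == 50)[0][0])
        defined = np.isfinite(landscape.r2[:, j50])
        valid = np.where(defined)[0]
        core = valid[landscape.time_grid[valid] >= 50]
        assert np.allclose(landscape.r2[core, j50], 1.0, atol=1e-10)
        # and lag 50 is the argmax for those windows
        argmax_lags = landscape.lag_grid[
            np.nanargmax(np.where(np.isfinite(landscape.r2[core]), landscape.r2[core], -1), axis=1)
        ]
        assert np.all(argmax_lags == 50)

    def test_dimensions_match_grid_construction(self):
        rng = np.random.default_rng(0)
        n = 2950
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        landscape = compute_landscape(a, b, _noise_config())
        assert landscape.r2.shape == (1475, 76)
        assert landscape.time_grid.size == n // 2
        assert landscape.lag_grid.size == 76
        assert landscape.lag_grid[0] == -74 and landscape.lag_grid[-1] == 76
        assert 0 in landscape.lag_grid and 50 in landscape.lag_grid

    def test_pure_noise_rarely_exceeds_cutoff(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 1200)
        b = rng.normal(0, 1, 1200)
        landscape = compute_landscape(a, b, _noise_config())
        defined = np.isfinite(landscape.r2)
        frac = np.mean(landscape.sig[defined] & (landscape.r2[defined] > 0.25))
        assert frac < 0.01

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            compute_landscape(np.ones(100), np.ones(100), _noise_config())

    def test_zero_variance_names_offending_window(self):
        a = np.zeros(400)
        b = np.zeros(400)
        with pytest.raises(ZeroVarianceError, match="frame"):
            compute_landscape(a, b, _noise_config(bandwidth=75))

    def test_swapping_series_negates_recovered_lag(self, params, best_config):
        from dyadsync import generate_base_pair, make_artificial, make_isolated
        from dyadsync.evaluation import intervals_to_binary

        emb, _ = generate_base_pair(params, sync=True, seed=4242)
        art = make_artificial(make_isolated(emb), lag=50)
        swapped = DyadSequence(
            id=art.id + "-swapped",
            condition=art.condition,
            sync_label=art.sync_label,
            a=art.b,
            b=art.a,
            reference=art.reference,
        )
        fwd = identify_msi(art, best_config, master_seed=5)
        rev = identify_msi(swapped, best_config, master_seed=5)
        lag_fwd = max(fwd, key=lambda i: i.duration).lag
        lag_rev = max(rev, key=lambda i: i.duration).lag
        assert lag_fwd == 50.0
        assert lag_rev == -50.0


def _manual_landscape(sig_cells, m=200, n_lags=76, r2_value=0.9, step=2):
    """Landscape fixture: r2/sig set only at the given (col, lag_index) cells."""
    r2 = np.zeros((m, n_lags))
    sig = np.zeros((m, n_lags), dtype=bool)
    for col, j in sig_cells:
        r2[col, j] = r2_value
        sig[col, j] = True
    k = 37
    lag_grid = np.array(list(range(-k * step, k * step + 1, step)) + [(k + 1) * step])
    return R2Landscape(
        r2=r2, sig=sig, time_grid=np.arange(0, m * step, step), lag_grid=lag_grid
    )


class TestPeakPick:
    def test_empty_landscape_yields_no_intervals(self):
        landscape = _manual_landscape([])
        assert peak_pick(landscape, _noise_config()) == []

    def test_single_block_yields_one_interval(self):
        cfg = _noise_config(bandwidth=75)
        cols = range(50, 150)
        landscape = _manual_landscape([(c, 40) for c in cols])
        intervals = peak_pick(landscape, cfg)
        assert len(intervals) == 1
        iv = intervals[0]
        # documented mapping of the window-start block [100, 298] to frames
        assert iv.start == 100 + 75 - 2
        assert iv.end == 298 + 2
        assert iv.lag == float(landscape.lag_grid[40])
        assert iv.mean_r2 == pytest.approx(0.9)

    def test_two_separated_blocks_yield_two_intervals(self):
        cfg = _noise_config(bandwidth=75)
        cells = [(c, 40) for c in range(10, 70)] + [(c, 40) for c in range(120, 180)]
        intervals = peak_pick(_manual_landscape(cells), cfg)
        assert len(intervals) == 2
        assert intervals[0].end <= intervals[1].start

    def test_short_chains_dropped_by_min_duration(self):
        cfg = _noise_config(bandwidth=75)
        # 30 columns -> 60-frame span -> mapped length 60 + 4 - 75 < MIN
        cells = [(c, 40) for c in range(10, 40)]
        assert peak_pick(_manual_landscape(cells), cfg) == []
        assert MIN_MSI_FRAMES == 13


class TestFilterByCutoff:
    def make(self, mean_r2):
        return SyncIntervalRecord(start=0, end=20, lag=0.0, mean_r2=mean_r2)

    def test_zero_cutoff_keeps_everything(self):
        ivs = [self.make(0.01), self.make(0.99)]
        assert filter_by_cutoff(ivs, 0.0) == ivs

    def test_strict_inequality(self):
        ivs = [self.make(0.2), self.make(0.25), self.make(0.3)]
        kept = filter_by_cutoff(ivs, 0.25)
        assert [iv.mean_r2 for iv in kept] == [0.3]

    def test_monotone_in_cutoff(self, rng):
        ivs = [self.make(v) for v in rng.uniform(0, 1, 50)]
        counts = [len(filter_by_cutoff(ivs, c)) for c in np.linspace(0, 0.99, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestIdentifyMsi:
    def test_artificial_sync_pair_recovers_construction_lag(
        self, artificial_dyads, best_config
    ):
        dyad = next(d for d in artificial_dyads if d.sync_label == "sync")
        intervals = identify_msi(dyad, best_config, master_seed=1)
        assert len(intervals) >= 1
        assert max(intervals, key=lambda i: i.duration).lag == 50.0

    def test_nosync_pair_low_over_identification(self, artificial_dyads, best_config):
        from dyadsync.evaluation import intervals_to_binary, pr_out

        rates = []
        for dyad in (d for d in artificial_dyads if d.sync_label == "nosync"):
            intervals = identify_msi(dyad, best_config, master_seed=1)
            rates.append(pr_out(intervals_to_binary(intervals, dyad.n_frames)))
        assert max(rates) < 0.05

    def test_all_zero_dyad_yields_nothing_at_high_cutoff(self):
        n = 1200
        zero = MotionEnergySeries(np.zeros(n), roi_area=100)
        dyad = DyadSequence(
            id="zeros",
            condition="artificial",
            sync_label="nosync",
            a=zero,
            b=MotionEnergySeries(np.zeros(n), roi_area=100),
            reference=IntervalSpec(10, 100),
        )
        cfg = _noise_config(r2_cutoff=0.3)
        assert identify_msi(dyad, cfg, master_seed=3) == []

    def test_deterministic_for_equal_master_seed(self, artificial_dyads, best_config):
        dyad = artificial_dyads[0]
        assert identify_msi(dyad, best_config, 7) == identify_msi(dyad, best_config, 7)

    def test_raising_cutoff_never_adds_detected_frames(self, artificial_dyads, best_config):
        from dataclasses import replace
        from dyadsync.evaluation import intervals_to_binary

        dyad = next(d for d in artificial_dyads if d.sync_label == "sync")
        frames = []
        for cutoff in (0.0, 0.1, 0.2, 0.25, 0.3):
            cfg = replace(best_config, r2_cutoff=cutoff)
            # keep the same noise seed so only the cutoff varies
            intervals = identify_msi(dyad, cfg, master_seed=11)
        # direct check on one landscape: filter at increasing cutoffs
        intervals = identify_msi(dyad, best_config, master_seed=11)
        for lo, hi in [(0.0, 0.1), (0.1, 0.25), (0.25, 0.3)]:
            n_lo = sum(iv.duration for iv in filter_by_cutoff(intervals, lo))
            n_hi = sum(iv.duration for iv in filter_by_cutoff(intervals, hi))
            assert n_hi <= n_lo
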