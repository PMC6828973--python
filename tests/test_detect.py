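"""FRP offset detection, onset maps and repetition aggregation."""

import numpy as np
import pytest

import flexrelax as fr
from flexrelax.detect import ChannelOnset, DetectionConfig, OnsetMap, baseline_stats
from flexrelax.errors import InputError

FS = 1024.0


def _make_env(env_matrix, angle=None, fs=FS, n_baseline=2048):
    """Wrap an envelope matrix in the containers detection expects."""
    n, k = env_matrix.shape
    lay = fr.GridLayout(n_rows=k + 1, n_cols=1, missing_corner=None)
    bt = fr.BipolarTrial(
        signals=env_matrix,  # unused by detection beyond the channel list
        channels=fr.enumerate_bipolar_channels(lay),
        sampling_rate=fs,
        angle=np.linspace(0, 90, n) if angle is None else angle,
        meta=fr.TrialMeta("s", "control", "left", 0),
        layout=lay,
    )
    return fr.EnvelopeTrial(envelopes=env_matrix, source=bt, filter_spec={})


def _seg(n, fs=FS):
    # baseline 1 s ending at 1.5 s, flexion 2..6 s, mvf 6..10 s, ext 10..n
    s = lambda x: int(x * fs)
    return fr.PhaseSegmentation(
        baseline=(s(0.5), s(1.5)),
        flexion=(s(2), s(6)),
        mvf=(s(6), s(10)),
        extension=(s(10), n),
        max_flexion_angle=90.0,
        flexion_duration=4.0,
        sampling_rate=fs,
    )


class TestBaselineStats:
    def test_constant_envelope(self):
        n = int(12 * FS)
        env = _make_env(np.full((n, 1), 3.0))
        bs = baseline_stats(env, _seg(n), 0)
        assert bs.mean == pytest.approx(3.0) and bs.sd == pytest.approx(0.0)

    def test_alternating_envelope_mean(self):
        n = int(12 * FS)
        x = np.empty((n, 1))
        x[::2, 0], x[1::2, 0] = 2.0, 4.0
        bs = baseline_stats(_make_env(x), _seg(n), 0)
        assert bs.mean == pytest.approx(3.0)

    def test_short_window_rejected(self):
        n = int(12 * FS)
        env = _make_env(np.ones((n, 1)))
        seg = _seg(n)
        bad = fr.PhaseSegmentation(
            baseline=(seg.baseline[0], seg.baseline[0] + 10),
            flexion=seg.flexion, mvf=seg.mvf, extension=seg.extension,
            max_flexion_angle=90.0, flexion_duration=4.0, sampling_rate=FS,
        )
        with pytest.raises(InputError):
            baseline_stats(env, bad, 0)

    def test_synthetic_baseline_level(self, processed_control, small_cohort):
        # quiet-standing envelope mean ~= baseline RMS x 2/pi (rectified
        # Gaussian), within 15%
        _, seg, _, env, _ = processed_control
        expected = small_cohort.config.baseline_amplitude * np.sqrt(2 / np.pi)
        means = [baseline_stats(env, seg, c).mean for c in range(59)]
        assert np.median(means) == pytest.approx(expected, rel=0.15)


def _step_env(n, drop_at, hi=10.0, lo=0.0, base=1.0, noise_sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = np.full(n, hi)
    x[: int(2 * FS)] = base + noise_sd * rng.standard_normal(int(2 * FS))
    x[drop_at:] = lo
    return np.abs(x)[:, None]


class TestDetectChannelOffset:
    def test_step_drop_detected_at_step(self):
        n = int(12 * FS)
        drop = int(4 * FS)  # mid-flexion
        env = _make_env(_step_env(n, drop))
        res = fr.detect_channel_offset(env, _seg(n), 0, DetectionConfig(axis="time"))
        assert res.present and res.onset_sample == drop
        assert res.onset_pct == pytest.approx(50.0, abs=1.0)

    def test_never_dropping_envelope_absent(self):
        n = int(12 * FS)
        env = _make_env(_step_env(n, drop_at=n))  # never drops
        res = fr.detect_channel_offset(env, _seg(n), 0)
        assert not res.present and res.onset_sample is None

    def test_never_active_flagged_with_zero_onset(self):
        n = int(12 * FS)
        x = np.full((n, 1), 0.0)
        x[: int(2 * FS), 0] = 1.0  # baseline tonic, then silence
        env = _make_env(x)
        res = fr.detect_channel_offset(env, _seg(n), 0)
        assert res.present and res.never_active and res.onset_pct == 0.0

    def test_reactivation_does_not_retract_detection(self):
        n = int(12 * FS)
        drop = int(3 * FS)
        x = _step_env(n, drop)
        x[int(5 * FS) :, 0] = 10.0  # comes back late in flexion
        env = _make_env(x)
        res = fr.detect_channel_offset(env, _seg(n), 0)
        assert res.present and res.onset_sample == drop

    def test_transient_dip_shorter_than_hold_ignored(self):
        n = int(12 * FS)
        x = _step_env(n, drop_at=int(5 * FS))
        dip = int(3 * FS)
        x[dip : dip + int(0.1 * FS), 0] = 0.0  # 100 ms dip < 250 ms hold
        env = _make_env(x)
        res = fr.detect_channel_offset(env, _seg(n), 0)
        assert res.onset_sample == int(5 * FS)

    def test_brute_force_scan_equivalence(self, small_cohort):
        # exhaustive per-sample scan with the same hold rule must agree on
        # every synthetic channel
        def brute(envv, thresh, f0, f1, hold_n):
            for i in range(f0, f1):
                if i + hold_n <= envv.size and np.all(envv[i : i + hold_n] < thresh):
                    return i
            return None

        cfg = DetectionConfig()
        n_checked = 0
        for trial in small_cohort.trials:
            seg = fr.segment_phases(trial.angle, trial.sampling_rate)
            env = fr.envelope(fr.derive_bipolar(trial))
            hold_n = max(1, int(round(cfg.hold_s * env.sampling_rate)))
            for ch in range(59):
                res = fr.detect_channel_offset(env, seg, ch, cfg)
                bs = baseline_stats(env, seg, ch)
                expect = brute(env.envelopes[:, ch], bs.mean + 3 * bs.sd, *seg.flexion, hold_n)
                got = res.onset_sample if res.present else None
                assert got == expect
                n_checked += 1
        assert n_checked == 3 * 59

    def test_raising_k_never_delays_onset(self, processed_control):
        # higher threshold => earlier-or-equal crossing
        _, seg, _, env, _ = processed_control
        for ch in range(0, 59, 7):
            r3 = fr.detect_channel_offset(env, seg, ch, DetectionConfig(k=3.0))
            r4 = fr.detect_channel_offset(env, seg, ch, DetectionConfig(k=4.0))
            if r3.present and r4.present:
                assert r4.onset_sample <= r3.onset_sample


class TestOnsetMap:
    def test_control_subject_all_channels_relax(self, processed_control):
        _, _, _, _, omap = processed_control
        assert omap.frp_present
        assert omap.fraction_channels_with_frp == 1.0

    def test_no_frp_subject_classified_absent(self, processed_no_frp):
        _, _, _, _, omap = processed_no_frp
        assert not omap.frp_present
        assert omap.fraction_channels_with_frp < 0.5

    @pytest.mark.parametrize("n_drop,expected", [(30, True), (29, False)])
    def test_majority_rule_boundary_at_30_of_59(self, n_drop, expected):
        n = int(12 * FS)
        cols = []
        for ch in range(59):
            drop = int(4 * FS) if ch < n_drop else n
            cols.append(_step_env(n, drop, seed=ch)[:, 0])
        lay = fr.GridLayout()
        bt = fr.BipolarTrial(
            signals=np.column_stack(cols),
            channels=fr.enumerate_bipolar_channels(lay),
            sampling_rate=FS,
            angle=np.linspace(0, 90, n),
            meta=fr.TrialMeta("s", "control", "left", 0),
            layout=lay,
        )
        env = fr.EnvelopeTrial(envelopes=bt.signals, source=bt, filter_spec={})
        omap = fr.build_onset_map(env, _seg(n))
        assert omap.frp_present is expected

    def test_fraction_exactly_half_is_absent(self):
        # strict '>50%' rule: 2 of 4 usable channels present -> absent
        n = int(12 * FS)
        cols = [_step_env(n, int(4 * FS) if ch < 2 else n, seed=ch)[:, 0] for ch in range(4)]
        lay = fr.GridLayout(n_rows=5, n_cols=1, missing_corner=None)
        bt = fr.BipolarTrial(
            signals=np.column_stack(cols),
            channels=fr.enumerate_bipolar_channels(lay),
            sampling_rate=FS,
            angle=np.linspace(0, 90, n),
            meta=fr.TrialMeta("s", "control", "left", 0),
            layout=lay,
        )
        env = fr.EnvelopeTrial(envelopes=bt.signals, source=bt, filter_spec={})
        omap = fr.build_onset_map(env, _seg(n))
        assert omap.fraction_channels_with_frp == 0.5
        assert omap.frp_present is False

    def test_qc_excluded_channels_out_of_denominator(self):
        n = int(12 * FS)
        cols = [_step_env(n, int(4 * FS) if ch < 3 else n, seed=ch)[:, 0] for ch in range(5)]
        lay = fr.GridLayout(n_rows=6, n_cols=1, missing_corner=None)
        bt = fr.BipolarTrial(
            signals=np.column_stack(cols),
            channels=fr.enumerate_bipolar_channels(lay),
            sampling_rate=FS,
            angle=np.linspace(0, 90, n),
            meta=fr.TrialMeta("s", "control", "left", 0),
            layout=lay,
            excluded={4: "low_snr"},
        )
        env = fr.EnvelopeTrial(envelopes=bt.signals, source=bt, filter_spec={})
        omap = fr.build_onset_map(env, _seg(n))
        # 3 of 4 usable channels present -> 0.75
        assert omap.fraction_channels_with_frp == pytest.approx(0.75)


def _mk_map(entries, excluded=None):
    channels = [
        ChannelOnset(present, None, pct, (i, 0))
        for i, (present, pct) in enumerate(entries)
    ]
    usable = [i for i in range(len(entries)) if i not in (excluded or {})]
    n_present = sum(1 for i in usable if channels[i].present)
    frac = n_present / len(usable)
    onsets = [channels[i].onset_pct for i in usable if channels[i].present]
    return OnsetMap(
        channels=channels,
        excluded=excluded or {},
        frp_present=frac > 0.5,
        fraction_channels_with_frp=frac,
        mean_onset_pct=float(np.mean(onsets)) if onsets else None,
    )


class TestAggregateRepetitions:
    def test_identical_maps_idempotent(self):
        m = _mk_map([(True, 40.0), (True, 60.0)])
        agg, _ = fr.aggregate_repetitions([m, m, m])
        assert agg.channels[0].onset_pct == pytest.approx(40.0)
        assert agg.fraction_channels_with_frp == 1.0

    def test_channel_mean_across_repetitions(self):
        maps = [_mk_map([(True, v)]) for v in (40.0, 50.0, 60.0)]
        agg, _ = fr.aggregate_repetitions(maps)
        assert agg.channels[0].onset_pct == pytest.approx(50.0)

    def test_majority_presence_with_one_absent_repetition(self):
        maps = [
            _mk_map([(True, 45.0)]),
            _mk_map([(True, 55.0)]),
            _mk_map([(False, None)]),
        ]
        agg, _ = fr.aggregate_repetitions(maps)
        assert agg.channels[0].present
        assert agg.channels[0].onset_pct == pytest.approx(50.0)

    def test_minority_presence_is_absent(self):
        maps = [
            _mk_map([(True, 45.0)]),
            _mk_map([(False, None)]),
            _mk_map([(False, None)]),
        ]
        agg, _ = fr.aggregate_repetitions(maps)
        assert not agg.channels[0].present

    def test_presence_tie_counts_as_present_with_warning(self):
        maps = [_mk_map([(True, 45.0)]), _mk_map([(False, None)])]
        with pytest.warns(UserWarning, match="tie"):
            agg, _ = fr.aggregate_repetitions(maps)
        assert agg.channels[0].present

    def test_amplitude_profiles_averaged(self):
        m = _mk_map([(True, 50.0)])
        _, prof = fr.aggregate_repetitions(
            [m, m], [np.array([10.0, 20.0]), np.array([30.0, 40.0])]
        )
        assert np.allclose(prof, [20.0, 30.0])
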