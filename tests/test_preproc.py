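"""Filtering, epoching, rejection and ICA artifact handling."""

import numpy as np
import pytest
import scipy.signal

from audibci import preproc, stimgen, synthdata
from audibci.preproc import (
    bandpass,
    epoch,
    fit_ica,
    reject_peak_to_peak,
    remove_components,
)
from audibci.stimgen import Kind
from audibci.synthdata import Recording


def sine_recording(freq, fs=1000.0, dur=10.0, amp=10.0, offset=0.0):
    t = np.arange(int(dur * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t) + offset
    return Recording(signal=sig[None, :], fs=fs, channels=["Cz"])


class TestBandpass:
    def test_passband_10hz_preserved_within_5pct(self):
        rec = bandpass(sine_recording(10.0), 0.5, 20.0, mode="zero_phase")
        steady = rec.signal[0, 2000:-2000]
        assert np.abs(steady).max() == pytest.approx(10.0, rel=0.05)

    def test_50hz_attenuated_at_least_20db(self):
        # measured on the designed transfer function itself
        sos = preproc._design_bandpass(0.5, 20.0, 1000.0)
        w, h = scipy.signal.sosfreqz(sos, worN=[50.0], fs=1000.0)
        assert 20 * np.log10(np.abs(h[0])) < -20

    def test_dc_offset_removed(self):
        rec = bandpass(sine_recording(10.0, offset=100.0), 0.5, 20.0, "zero_phase")
        assert np.abs(rec.signal[0, 4000:6000].mean()) < 1.0

    def test_causal_mode_is_causal(self):
        pulse = np.zeros((1, 1000))
        pulse[0, 500] = 1.0
        rec = Recording(signal=pulse, fs=1000.0, channels=["Cz"])
        out = bandpass(rec, 0.5, 20.0, mode="causal")
        assert np.abs(out.signal[0, :500]).max() == 0.0

    @pytest.mark.parametrize("low,high", [(20.0, 0.5), (0.0, 20.0), (0.5, 600.0)])
    def test_invalid_edges_raise(self, low, high):
        with pytest.raises(ValueError):
            bandpass(sine_recording(10.0), low, high)


class TestEpoch:
    @pytest.fixture(scope="class")
    def block_recording(self):
        plan = stimgen.generate_session(1, 0, seed=3)
        cfg = synthdata.healthy_config(seed=3, noise_rms=0.0)
        rec = synthdata.simulate_session(plan, cfg)
        return rec, [b.target for b in plan.blocks]

    def test_healthy_block_epoch_counts_and_lengths(self, block_recording):
        rec, targets = block_recording
        es = epoch(rec, {Kind.STANDARD: 0.5, Kind.DEVIANT: 0.75}, targets)
        assert es.data[Kind.STANDARD].shape == (60, 32, 500)
        assert es.data[Kind.DEVIANT].shape == (12, 32, 750)

    def test_attended_labels_follow_block_target(self, block_recording):
        rec, targets = block_recording
        es = epoch(rec, {Kind.STANDARD: 0.5, Kind.DEVIANT: 0.75}, targets)
        att = es.info[es.info["attended"] == True]  # noqa: E712
        assert set(att["stream"]) == {targets[0].value}

    def test_empty_marker_list(self):
        rec = Recording(signal=np.zeros((1, 100)), fs=100.0, channels=["Cz"])
        es = epoch(rec, {Kind.STANDARD: 0.1})
        assert es.n_epochs == 0

    def test_event_near_end_of_recording_dropped(self):
        sig = np.zeros((1, 1000))
        rec = Recording(
            signal=sig, fs=1000.0, channels=["Cz"], events=[(100, 11), (995, 11)]
        )
        es = epoch(rec, {Kind.STANDARD: 0.5})
        assert es.n_epochs == 1

    def test_no_baseline_correction(self):
        sig = np.full((1, 1000), 5.0)
        rec = Recording(signal=sig, fs=1000.0, channels=["Cz"], events=[(500, 11)])
        es = epoch(rec, {Kind.STANDARD: (-0.1, 0.1)})
        assert np.allclose(es.data[Kind.STANDARD], 5.0)


class TestRejectPeakToPeak:
    def make_epochs(self, n, rng, spiked=()):
        sig = rng.standard_normal((1, 1000 * (n + 1)))
        events = [(1000 * i, 11) for i in range(n)]
        for i in spiked:
            sig[0, 1000 * i + 50] += 500.0
        rec = Recording(signal=sig, fs=1000.0, channels=["Cz"], events=events)
        return epoch(rec, {Kind.STANDARD: 0.5})

    def test_15pct_of_100_removes_exactly_15(self, rng):
        es = reject_peak_to_peak(self.make_epochs(100, rng), 0.15)
        assert es.info["kept"].sum() == 85

    def test_fraction_zero_is_identity(self, rng):
        es = reject_peak_to_peak(self.make_epochs(20, rng), 0.0)
        assert es.info["kept"].all()

    def test_planted_spikes_are_the_removed_set(self, rng):
        spiked = {3, 11, 17, 20, 28, 35, 42, 49, 55, 61, 68, 74, 83, 90, 97}
        es = reject_peak_to_peak(self.make_epochs(100, rng, spiked), 0.15)
        removed = set(es.info.index[~es.info["kept"]])
        assert removed == spiked

    def test_kept_count_formula(self, rng):
        for n, frac in [(10, 0.15), (7, 0.3), (13, 0.5)]:
            es = reject_peak_to_peak(self.make_epochs(n, rng), frac)
            assert es.info["kept"].sum() == int(np.ceil((1 - frac) * n))

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            reject_peak_to_peak(self.make_epochs(5, rng), 1.0)


def blink_recording(seed, fs=250.0, dur=60.0):
    """Noise + a known blink source with frontal topography."""
    from audibci.io_formats import MONTAGES, montage_positions

    rng = np.random.default_rng(seed)
    channels = MONTAGES["acticap32"][:16]  # includes Fp1/Fp2
    n = int(dur * fs)
    n_src = len(channels)
    mixing = rng.standard_normal((n_src, n_src))
    sources = rng.standard_normal((n_src, n))
    sig = mixing @ sources
    pos = montage_positions(channels)
    blink_topo = 60.0 * np.exp(
        -np.sum((pos - [0.0, 1.05]) ** 2, axis=1) / (2 * 0.55**2)
    )
    blink_tc = np.zeros(n)
    width = int(0.3 * fs)
    t = np.arange(width) / fs
    wave = np.exp(-(((t - 0.15) / 0.06) ** 2))
    starts = rng.integers(0, n - width, size=15)
    for s in starts:
        blink_tc[s : s + width] += wave
    sig = sig + np.outer(blink_topo, blink_tc)
    rec = Recording(signal=sig, fs=fs, channels=channels)
    return rec, blink_tc


class TestIca:
    def test_blink_component_recovered_and_removed(self):
        rec, blink_tc = blink_recording(seed=1)
        ica = fit_ica(rec, seed=0)
        src = ica.sources(rec)
        corr = np.abs(
            [np.corrcoef(s, blink_tc)[0, 1] for s in src]
        )
        best = int(np.argmax(corr))
        assert corr[best] > 0.9
        cleaned = remove_components(rec, ica, [best])
        fp = rec.channels.index("Fp1")
        mask = blink_tc > 0.5
        before = np.abs(rec.signal[fp, mask]).mean()
        after = np.abs(cleaned.signal[fp, mask]).mean()
        assert after < 0.2 * before
        # and the blink score ranks that component highest
        assert ica.scores["blink"].idxmax() == best

    def test_empty_removal_is_identity(self):
        rec, _ = blink_recording(seed=2)
        ica = fit_ica(rec, seed=0)
        out = remove_components(rec, ica, [])
        assert np.allclose(out.signal, rec.signal)

    def test_fit_deterministic_given_seed(self):
        rec, _ = blink_recording(seed=3)
        a = fit_ica(rec, seed=5)
        b = fit_ica(rec, seed=5)
        assert np.allclose(a.unmixing, b.unmixing)

    def test_no_flags_on_artifact_free_data(self):
        """Null simulations should not trigger the default thresholds."""
        from audibci.preproc import suggest_artifact_components

        for seed in range(10):
            rng = np.random.default_rng(seed)
            channels = synthdata.MONTAGES["vamp16"]
            sig = rng.standard_normal((16, 64)) @ rng.standard_normal((64, 5000))
            rec = Recording(signal=sig, fs=250.0, channels=channels)
            ica = fit_ica(rec, n_components=8, seed=seed)
            assert suggest_artifact_components(ica) == []

    def test_too_many_components_rejected(self):
        rec, _ = blink_recording(seed=4)
        with pytest.raises(ValueError):
            fit_ica(rec, n_components=99, seed=0)


class TestComponentContrast:
    def test_zero_variance_component_raises(self, small_session):
        _, rec, cal, _ = small_session
        filtered = bandpass(rec, 0.5, 20.0, "zero_phase")
        es = epoch(filtered, {Kind.STANDARD: 0.5, Kind.DEVIANT: 0.75}, cal)
        ica = fit_ica(filtered, n_components=6, seed=0)
        dead = preproc.IcaDecomposition(
            unmixing=np.zeros_like(ica.unmixing),
            mixing=np.zeros_like(ica.mixing),
            mean=ica.mean,
            channels=ica.channels,
        )
        with pytest.raises(ValueError, match="degenerate|zero-variance"):
            preproc.component_erp_contrast(es, dead, 0, n_permutations=200)

    def test_injected_attended_deflection_detected(self, small_session):
        """A strong attended-only deflection yields a significant cluster."""
        _, rec, cal, _ = small_session
        filtered = bandpass(rec, 0.5, 20.0, "zero_phase")
        es = epoch(filtered, {Kind.STANDARD: 0.5, Kind.DEVIANT: 0.75}, cal)
        ica = fit_ica(filtered, n_components=6, seed=0)
        # inject a deflection into attended standard epochs on one component
        att = es.info[(es.info["kind"] == "STANDARD") & (es.info["attended"] == True)]  # noqa: E712
        data = es.data[Kind.STANDARD]
        scale = 3 * data.std()
        pattern = ica.mixing[:, 0]
        sl = slice(int(0.2 * es.fs), int(0.3 * es.fs))
        for r in att["kind_row"]:
            data[r, :, sl] += scale * pattern[:, None]
        res = preproc.component_erp_contrast(
            es, ica, 0, n_permutations=500, seed=1
        )
        window_mask = np.zeros_like(res.mask)
        window_mask[:, sl] = True
        assert (res.mask & window_mask).any()
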