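"""Classifier fusion, calibration, cross-validation and replay."""

import numpy as np
import pytest

from audibci import decoder, io_formats
from audibci.decoder import (
    CONDITIONS,
    ConditionClassifier,
    PreparedBlock,
    build_features,
    decide_block,
    fuse_posteriors,
)
from audibci.stimgen import Kind, Stream
from conftest import make_session


class TestFusion:
    def test_three_pinned_classifiers_reduce_to_fourth(self):
        for p in (0.01, 0.3, 0.5, 0.77, 0.99):
            fused = fuse_posteriors(
                {"STD_YES": 0.5, "STD_NO": 0.5, "DEV_YES": 0.5, "DEV_NO": p}
            )
            assert fused == pytest.approx(p, abs=1e-12)

    def test_hand_computed_product_08_case(self):
        # 0.8^4 / (0.8^4 + 0.2^4) = 0.4096 / 0.4112
        fused = fuse_posteriors({k: 0.8 for k in ("a", "b", "c", "d")})
        expected = 0.8**4 / (0.8**4 + 0.2**4)
        assert fused == pytest.approx(expected, abs=1e-12)
        assert fused == pytest.approx(0.99611, abs=5e-5)

    def test_all_uninformative_gives_half(self):
        assert fuse_posteriors({k: 0.5 for k in "abcd"}) == pytest.approx(0.5)

    def test_label_swap_symmetry(self):
        """Swapping YES/NO everywhere flips the fused posterior exactly."""
        ps = {"a": 0.9, "b": 0.7, "c": 0.2, "d": 0.55}
        swapped = {k: 1 - v for k, v in ps.items()}
        assert fuse_posteriors(ps) + fuse_posteriors(swapped) == pytest.approx(
            1.0, abs=1e-12
        )


class TestConditionClassifier:
    def fit_pair(self, rng, flip=False):
        x = rng.standard_normal((14, 20))
        y = np.arange(14) % 2 == 0
        x[y] += 0.5
        cond = (Stream.YES, Kind.STANDARD)
        return ConditionClassifier.fit(x, ~y if flip else y, cond), x

    def test_posterior_label_antisymmetry(self, rng):
        clf, x = self.fit_pair(rng)
        clf_flipped, _ = self.fit_pair(
            np.random.default_rng(0), flip=True
        )
        for row in x[:5]:
            assert clf.posterior(row) + clf_flipped.posterior(row) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_single_class_raises(self, rng):
        x = rng.standard_normal((6, 4))
        with pytest.raises(ValueError, match="single-class"):
            ConditionClassifier.fit(
                x, np.ones(6, bool), (Stream.YES, Kind.STANDARD)
            )

    def test_null_features_decide_at_chance(self, rng):
        """Uninformative features: long-run YES rate stays near 0.5.

        Any single calibrated model carries a random decision bias, so
        the rate is aggregated over several independently calibrated
        null models (10 models x 100 blocks)."""
        yes, n = 0, 0
        for _ in range(10):
            y = np.arange(40) % 2 == 0
            clfs = {
                cond: ConditionClassifier.fit(
                    rng.standard_normal((40, 10)), y, cond
                )
                for cond in CONDITIONS
            }
            for _ in range(100):
                posts = {
                    decoder.CONDITION_NAMES[c]: clfs[c].posterior(
                        rng.standard_normal(10)
                    )
                    for c in CONDITIONS
                }
                yes += fuse_posteriors(posts) > 0.5
                n += 1
        assert 0.45 <= yes / n <= 0.55


class TestFitAndDecide:
    def test_feature_dimension_arithmetic(self, small_session, small_model):
        """feature length == n_filters x round(window * fs / decim)."""
        _, rec, cal, _ = small_session
        model, cfg = small_model
        ps = decoder.prepare_session(rec, cfg, cal)
        feats = build_features(
            ps.blocks[0], model.banks, model.n_filters, ps.windows
        )
        fs_dec = rec.fs / cfg.decim
        for (stream, kind), v in feats.items():
            expected = model.n_filters * int(round(cfg.windows[kind.value] * fs_dec))
            assert v.shape == (expected,)

    def test_single_epoch_average_equals_epoch(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 100))
        block = PreparedBlock(
            data=data, target=Stream.YES,
            events=[(10, s, k, 0) for s in Stream for k in Kind],
        )
        avg = decoder._condition_average(
            block, {Kind.STANDARD: 20, Kind.DEVIANT: 30}, (Stream.YES, Kind.STANDARD)
        )
        assert np.array_equal(avg, data[:, 10:30])

    def test_missing_condition_error_names_it(self, small_model):
        model, _ = small_model
        block = PreparedBlock(
            data=np.zeros((16, 500)), target=Stream.YES,
            events=[(0, Stream.YES, Kind.STANDARD, 0),
                    (30, Stream.NO, Kind.STANDARD, 0),
                    (60, Stream.YES, Kind.DEVIANT, 0)],
        )
        with pytest.raises(ValueError, match="DEV_NO"):
            decide_block(model, block)

    def test_missing_condition_pinned_when_requested(self, small_model):
        model, _ = small_model
        rng = np.random.default_rng(0)
        block = PreparedBlock(
            data=rng.standard_normal((16, 500)), target=Stream.YES,
            events=[(0, Stream.YES, Kind.STANDARD, 0),
                    (30, Stream.NO, Kind.STANDARD, 0),
                    (60, Stream.YES, Kind.DEVIANT, 0)],
        )
        d = decide_block(model, block, on_missing="pin")
        assert d.posteriors["DEV_NO"] == 0.5

    def test_refit_identical_parameters(self, small_session):
        _, rec, cal, _ = small_session
        cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
        a = decoder.fit(rec, cal, cfg)
        b = decoder.fit(rec, cal, cfg)
        for cond in CONDITIONS:
            assert np.array_equal(
                a.classifiers[cond].weights, b.classifiers[cond].weights
            )

    def test_all_yes_calibration_raises_single_class(self):
        _, rec, cal, _ = make_session(
            seed=13, n_cal=4, targets_override=None
        ) if False else (None, None, None, None)
        # build a 4-block all-YES session explicitly
        from audibci import stimgen, synthdata

        plan = stimgen.generate_session(
            4, 0, seed=13, targets=[Stream.YES] * 4, montage_name="vamp16"
        )
        cfg = synthdata.healthy_config(seed=13, fs=250.0, montage="vamp16")
        rec = synthdata.simulate_session(plan, cfg)
        with pytest.raises(ValueError, match="single-class"):
            decoder.fit(rec, [Stream.YES] * 4, io_formats.PipelineConfig(n_xdawn_filters=2))

    def test_too_few_blocks_raise(self, small_session):
        _, rec, cal, _ = small_session
        from audibci.cli import _calibration_part

        rec3 = _calibration_part(rec, 3)
        with pytest.raises(ValueError, match=">= 4"):
            decoder.fit(rec3, cal[:3], io_formats.PipelineConfig(n_xdawn_filters=2))

    def test_model_json_round_trip(self, small_model, tmp_path):
        model, _ = small_model
        model.save(tmp_path / "m.json")
        back = decoder.DecoderModel.load(tmp_path / "m.json")
        assert back.n_filters == model.n_filters
        for cond in CONDITIONS:
            assert np.allclose(
                back.classifiers[cond].weights, model.classifiers[cond].weights
            )
        assert np.allclose(
            back.banks[Kind.STANDARD].filters, model.banks[Kind.STANDARD].filters
        )


class TestCrossValidation:
    def test_two_block_degenerate_case_runs(self):
        _, rec, cal, _ = make_session(seed=17, n_cal=2)
        cfg = io_formats.PipelineConfig(n_xdawn_filters=1)
        acc, decisions = decoder.cross_validate(rec, cal, cfg)
        assert acc in {0.0, 0.5, 1.0}
        assert len(decisions) == 2

    def test_shuffled_labels_give_chance_accuracy(self):
        """Destroying the label-signal link: accuracy within the 95%
        binomial interval of 0.5."""
        from scipy.stats import binom

        _, rec, cal, _ = make_session(seed=19, n_cal=12)
        rng = np.random.default_rng(1)
        shuffled = [cal[i] for i in rng.permutation(len(cal))]
        # keep the shuffle non-trivial
        while shuffled == cal:
            shuffled = [cal[i] for i in rng.permutation(len(cal))]
        cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
        acc, _ = decoder.cross_validate(rec, shuffled, cfg)
        lo, hi = binom.interval(0.95, 12, 0.5)
        assert lo / 12 <= acc <= hi / 12

    def test_high_snr_calibration_cv(self):
        _, rec, cal, _ = make_session(seed=23, n_cal=10)
        cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
        acc, _ = decoder.cross_validate(rec, cal, cfg)
        assert acc >= 0.8


class TestReplay:
    def test_replay_matches_batch_decisions_exactly(self):
        _, rec, cal, test = make_session(seed=29, n_cal=8, n_test=4)
        from audibci.cli import _calibration_part, _test_part

        cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
        model = decoder.fit(_calibration_part(rec, 8), cal, cfg)
        test_rec = _test_part(rec, 8)
        decisions, running = decoder.replay_online(model, test_rec, test)
        ps = decoder.prepare_session(test_rec, cfg, test, filter_mode="causal")
        batch = [decoder.decide_block(model, b, i) for i, b in enumerate(ps.blocks)]
        assert [d.decision for d in decisions] == [d.decision for d in batch]
        assert np.allclose(
            [d.fused for d in decisions], [d.fused for d in batch]
        )
        assert len(running) == len(decisions)

    def test_empty_test_returns_empty(self, small_model):
        from audibci.synthdata import Recording

        model, _ = small_model
        rec = Recording(
            signal=np.zeros((16, 1000)), fs=250.0,
            channels=model.channels, events=[],
        )
        decisions, running = decoder.replay_online(model, rec, [])
        assert decisions == [] and running == []

    def test_pool_total_equals_unrestricted(self):
        _, rec, cal, _ = make_session(seed=31, n_cal=8)
        cfg = io_formats.PipelineConfig(n_xdawn_filters=2)
        a, da = decoder.cross_validate(rec, cal, cfg, pool="TOTAL")
        b, db = decoder.cross_validate(rec, cal, cfg)
        assert a == b
        assert [d.decision for d in da] == [d.decision for d in db]
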