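"""Reader side: alignment, SNR normalization, features, regression, decode."""

import numpy as np
import pandas as pd
import pytest

from chemsteg.chemchannel import SpectrumGrid, deposit, simulate_substrate
from chemsteg.framing import make_picklist
from chemsteg.geometry import GridGeometry
from chemsteg.pipeline import (
    RunConfig,
    ChannelConfig,
    build_library,
    encode_key,
    decode_run,
    pilot_levels,
    simulate_run,
)
from chemsteg.readout import (
    LockMassError,
    ReadoutModel,
    feature_matrix,
    fit_readout,
    lock_align,
    lock_align_grid,
    select_features,
    snr_normalize,
)

LOCK = 575.0788


class TestLockAlign:
    def spectrum(self, shift=0.0):
        mz = np.array([200.0, LOCK + shift, 800.0])
        inten = np.array([1e4, 1e9, 1e3])
        return mz, inten

    def test_aligned_spectrum_gets_zero_shift(self):
        mz, inten = self.spectrum()
        out, shift = lock_align(mz, inten, LOCK)
        assert shift == 0.0
        assert np.array_equal(out, mz)

    def test_injected_shift_recovered(self):
        mz, inten = self.spectrum(shift=0.003)
        out, shift = lock_align(mz, inten, LOCK)
        assert shift == pytest.approx(-0.003)
        assert out[1] == pytest.approx(LOCK)

    def test_idempotent(self):
        mz, inten = self.spectrum(shift=-0.01)
        once, _ = lock_align(mz, inten, LOCK)
        twice, shift2 = lock_align(once, inten, LOCK)
        assert shift2 == 0.0
        assert np.array_equal(once, twice)

    def test_missing_lock_peak_raises(self):
        with pytest.raises(LockMassError):
            lock_align(np.array([200.0, 300.0]), np.array([1.0, 1.0]), LOCK)


class TestSnrNormalize:
    def test_constructed_peak_at_five_sigma(self, rng):
        bg = rng.normal(1000.0, 100.0, 400)
        bg = np.clip(bg, 1, None)
        mu, sigma = bg[bg <= np.quantile(bg, 0.25)].mean(), bg[
            bg <= np.quantile(bg, 0.25)
        ].std()
        spectrum = np.concatenate([bg, [mu + 5 * sigma]])
        mz = np.linspace(150, 900, spectrum.size)
        norm = snr_normalize(mz, spectrum)
        assert norm.snr[-1] == pytest.approx(5.0, abs=0.2)

    def test_background_maps_to_zero_mean_unit_std(self, small_grid):
        norm = snr_normalize(small_grid.mz[0], small_grid.intensity[0])
        inten = small_grid.intensity[0]
        bg = inten <= np.quantile(inten, 0.25)
        assert np.mean(norm.snr[bg]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(norm.snr[bg]) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            snr_normalize(np.linspace(150, 900, 20), np.full(20, 7.0))

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            snr_normalize(np.array([150.0, 200.0]), np.array([1.0, 2.0]))


class TestSelectFeatures:
    def test_low_floor_keeps_everything(self, small_grid):
        all_masses, _ = select_features(small_grid, floor=-np.inf)
        some_masses, _ = select_features(small_grid, floor=2.0)
        assert some_masses.size <= all_masses.size

    def test_floor_above_max_raises_with_hint(self, small_grid):
        with pytest.raises(ValueError, match="lower the floor"):
            select_features(small_grid, floor=1e9)

    def test_feature_sets_are_nested_in_floor(self, small_grid):
        m3, _ = select_features(small_grid, floor=3.0)
        m2, _ = select_features(small_grid, floor=2.0)
        assert set(np.round(m3, 4)) <= set(np.round(m2, 4))


def _labelled_binary_grid(seed=77, n_loc=64):
    """Noise-free deposited grid + labels: perfectly separable L=2 case."""
    geom = GridGeometry(rows=8, cols=8)
    cfg = RunConfig(geometry=geom, n_extracts=1, levels=2, seed=seed)
    lib = build_library(cfg)
    levels = pilot_levels(3, 1, n_loc, 2)
    pk = make_picklist(levels, geom)
    grid = simulate_substrate(seed, geom, cfg.substrate)
    treated = deposit(grid, pk, lib)  # noiseless
    labels = pd.DataFrame(
        {
            "location": np.arange(n_loc),
            "extract_id": 0,
            "level": levels[0],
        }
    )
    return treated, labels


class TestFitReadout:
    def test_noiseless_binary_grid_is_perfectly_separable(self):
        grid, labels = _labelled_binary_grid()
        model = fit_readout(grid, labels, levels=2, split=0.5, seed=0)
        t, p = model.heldout_scatter(0)
        assert np.mean(np.round(p) == t) == 1.0

    def test_permuted_labels_give_chance_accuracy(self, rng):
        grid, labels = _labelled_binary_grid()
        labels = labels.assign(level=rng.permutation(labels["level"].to_numpy()))
        model = fit_readout(grid, labels, levels=2, split=0.5, seed=0)
        t, p = model.heldout_scatter(0)
        acc = np.mean(np.round(np.clip(p, 0, 1)) == t)
        assert acc < 0.75  # no better than guessing, up to sampling noise

    def test_single_level_training_rejected(self):
        grid, labels = _labelled_binary_grid()
        labels["level"] = 1
        with pytest.raises(ValueError, match="distinct"):
            fit_readout(grid, labels, levels=2, split=0.5, seed=0)

    def test_model_round_trips_through_archive(self, tmp_path):
        grid, labels = _labelled_binary_grid()
        model = fit_readout(grid, labels, levels=2, split=0.5, seed=0)
        path = tmp_path / "readout.joblib"
        model.save(path)
        loaded = ReadoutModel.load(path)
        assert np.allclose(loaded.predict(grid), model.predict(grid))
        tsv = tmp_path / "features.tsv"
        model.export_features(tsv)
        assert len(pd.read_csv(tsv, sep="\t")) == model.feature_masses.size


class TestDecode:
    def test_zero_noise_channel_recovers_exactly(self):
        from chemsteg.chemchannel import ExtractModel

        key = "deadbeefdeadbeef"  # 64-bit hex payload
        cfg = RunConfig(
            geometry=GridGeometry(rows=10, cols=10),
            n_extracts=2,
            levels=4,
            seed=9,
            extract=ExtractModel(ambient_presence_prob=0.0),
            channel=ChannelConfig(
                write_sigma=0.0,
                failure_rate=0.0,
                read_sigma=0.0,
                shot_scale=0.0,
                mz_sigma=0.0,
                calibration_sigma=0.0,
            ),
        )
        enc = encode_key(key, cfg)
        grid = simulate_run(enc.picklist, cfg)
        recovered, stats, _ = decode_run(grid, enc.plan, cfg, true_codeword=enc.codeword)
        assert stats["raw_error_rate"] == 0.0
        assert recovered == key

    def test_plan_grid_mismatch_rejected(self, small_grid):
        from chemsteg.bitcodec import TurboConfig
        from chemsteg.framing import FramePlan
        from chemsteg.readout import decode_message

        grid, labels = _labelled_binary_grid()
        model = fit_readout(grid, labels, levels=2, split=0.5, seed=0)
        plan = FramePlan(n_extracts=5, n_locations=10, levels=2)
        with pytest.raises(ValueError):
            decode_message(grid, plan, model, TurboConfig())
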