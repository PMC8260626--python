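"""Channel simulator: substrate statistics, extracts, deposition, acquisition."""

import numpy as np
import pandas as pd
import pytest

from chemsteg.chemchannel import (
    ExtractModel,
    SpectrumGrid,
    SubstrateModel,
    acquire,
    ambient_interference,
    deposit,
    level_multipliers,
    mean_spectrum,
    simulate_extracts,
    simulate_substrate,
    substrate_catalog,
)
from chemsteg.framing import make_picklist
from chemsteg.geometry import GridGeometry


class TestSubstrate:
    def test_mean_spectrum_peaks_at_lock_mass(self, small_grid, substrate_model):
        masses, mean_int, _ = mean_spectrum(small_grid)
        assert masses[np.argmax(mean_int)] == pytest.approx(
            substrate_model.lock_mass, abs=0.01
        )

    def test_catalog_base_intensities_decay_monotonically(self, substrate_model):
        cat = substrate_catalog(substrate_model)
        sorted_desc = np.sort(cat["base_intensity"])[::-1]
        assert np.all(np.diff(sorted_desc) <= 0)
        assert cat["base_intensity"].max() == pytest.approx(1e9)

    def test_location_unique_fraction_matches_model(self, substrate_model):
        # Bernoulli assignment: realized fraction within 4 binomial sigmas
        counts = []
        for seed in range(5):
            g = simulate_substrate(seed, GridGeometry(rows=6, cols=6), substrate_model)
            counts.append(g.meta["n_unique_masses"] / g.meta["catalog_size"])
        f = substrate_model.unique_mass_fraction
        n = 4050
        tol = 4 * np.sqrt(f * (1 - f) / n)
        assert abs(np.mean(counts) - f) < tol

    def test_same_seed_reproduces_grid(self, small_geometry, substrate_model):
        a = simulate_substrate(7, small_geometry, substrate_model)
        b = simulate_substrate(7, small_geometry, substrate_model)
        for i in range(a.n_locations):
            assert np.array_equal(a.mz[i], b.mz[i])
            assert np.array_equal(a.intensity[i], b.intensity[i])

    def test_spectra_are_sorted_with_nonnegative_intensity(self, small_grid):
        for mz, inten in zip(small_grid.mz, small_grid.intensity):
            assert np.all(np.diff(mz) > 0)
            assert np.all(inten >= 0)


class TestDilution:
    def test_binary_multipliers(self):
        assert level_multipliers(2).tolist() == [0.0, 1.0]

    def test_log_spacing_over_two_decades(self):
        m = level_multipliers(32)
        assert m[0] == 0.0
        assert m[-1] == pytest.approx(1.0)
        assert m[1] == pytest.approx(1e-2)
        ratios = m[2:] / m[1:-1]
        assert np.allclose(ratios, ratios[0])

    def test_dilution_series_strictly_decreasing(self, library):
        s = library.dilution_series
        assert np.all(np.diff(s) < 0)


class TestExtracts:
    def test_single_extract_allowed(self, extract_model):
        lib = simulate_extracts(5, 1, extract_model)
        assert lib.n_extracts == 1

    def test_unique_mass_sets_pairwise_disjoint(self, library):
        sets = [set(np.round(s.unique_mz, 4)) for s in library.signatures]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_conventional_identifying_masses_on_first_extract(self, library):
        assert 184.07 in library.signatures[0].unique_mz
        assert 478.33 in library.signatures[0].unique_mz

    def test_signature_scale_is_trace_level(self, library):
        # strongest identifying mass ~1e5 against the 1e9 background dye
        assert library.signatures[0].unique_intensity.max() == pytest.approx(1e5)

    def test_invalid_count_rejected(self, extract_model):
        with pytest.raises(ValueError):
            simulate_extracts(5, 0, extract_model)


class TestDeposit:
    def geometry(self):
        return GridGeometry(rows=4, cols=4)

    def test_empty_picklist_leaves_grid_unchanged(self, library):
        g = simulate_substrate(3, self.geometry(), library.model.substrate)
        out = deposit(g, pd.DataFrame(columns=["extract_id"]), library)
        for i in range(g.n_locations):
            assert np.array_equal(out.intensity[i], g.intensity[i])

    def test_noiseless_deposit_is_exactly_additive(self, library):
        g = simulate_substrate(3, self.geometry(), library.model.substrate)
        mat = np.zeros((1, 1), int)
        mat[0, 0] = library.levels - 1  # full strength
        pk = make_picklist(mat, self.geometry())
        out = deposit(g, pk, library)
        sig = library.signatures[0]
        added = out.intensity[0].sum() - g.intensity[0].sum()
        assert added == pytest.approx(sig.all_intensity.sum(), rel=1e-9)
        # untouched location is bit-identical
        assert np.array_equal(out.intensity[5], g.intensity[5])

    def test_two_deposits_superpose_linearly(self, library):
        g = simulate_substrate(3, self.geometry(), library.model.substrate)
        top = library.levels - 1
        pk_a = make_picklist(np.array([[top]]), self.geometry())
        pk_b = pd.concat(
            [make_picklist(np.array([[top]]), self.geometry()),
             make_picklist(np.array([[0], [top]]), self.geometry())],
            ignore_index=True,
        )
        once = deposit(g, pk_a, library)
        twice = deposit(g, pk_b, library)
        gain_once = once.intensity[0].sum() - g.intensity[0].sum()
        gain_twice = twice.intensity[0].sum() - g.intensity[0].sum()
        expected = (
            library.signatures[0].all_intensity.sum()
            + library.signatures[1].all_intensity.sum()
        )
        assert gain_twice == pytest.approx(expected, rel=1e-9)
        assert gain_twice > gain_once

    def test_unknown_extract_rejected(self, library):
        g = simulate_substrate(3, self.geometry(), library.model.substrate)
        pk = make_picklist(np.array([[1]]), self.geometry())
        pk["extract_id"] = 99
        with pytest.raises(KeyError):
            deposit(g, pk, library)


class TestAcquire:
    def one_peak_grid(self):
        geom = GridGeometry(rows=1, cols=1)
        return SpectrumGrid(
            geometry=geom,
            cells=np.array([[0, 0]]),
            mz=[np.array([500.0])],
            intensity=[np.array([1e6])],
        )

    def test_noise_off_is_identity(self):
        g = self.one_peak_grid()
        out = acquire(g, 1, seed=0, read_sigma=0, shot_scale=0, mz_sigma=0,
                      calibration_sigma=0)
        assert np.array_equal(out.intensity[0], g.intensity[0])
        assert np.array_equal(out.mz[0], g.mz[0])

    def test_averaging_shrinks_noise_as_sqrt_k(self):
        # empirical std ratio between k=4 and k=16 averaging ~ sqrt(4) = 2
        g = self.one_peak_grid()
        outs = {k: [] for k in (4, 16)}
        for rep in range(200):
            for k in (4, 16):
                out = acquire(g, k, seed=1000 * k + rep, read_sigma=0.4,
                              shot_scale=0, mz_sigma=0, calibration_sigma=0)
                outs[k].append(out.intensity[0][0])
        ratio = np.std(outs[4]) / np.std(outs[16])
        assert 1.6 < ratio < 2.5

    def test_invalid_read_count_rejected(self):
        with pytest.raises(ValueError):
            acquire(self.one_peak_grid(), 0)


class TestAmbientInterference:
    def test_identifying_masses_appear_in_untreated_background(self, library):
        g = simulate_substrate(11, GridGeometry(rows=6, cols=6), library.model.substrate)
        out = ambient_interference(g, library, seed=4)
        umz = library.unique_masses()
        hits = 0
        for j in range(out.n_locations):
            d = np.min(np.abs(out.mz[j][:, None] - umz[None, :]), axis=0)
            hits += int(np.sum(d < 0.005))
        expected = library.model.ambient_presence_prob * umz.size * out.n_locations
        assert 0.5 * expected < hits < 1.5 * expected
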