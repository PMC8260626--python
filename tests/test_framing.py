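"""Framing layer: binarization, interleaving, symbols, picklists, capacity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemsteg.bitcodec import TurboConfig, bsc_llr, turbo_decode, turbo_encode
from chemsteg.framing import (
    FramePlan,
    binarize_key,
    capacity,
    debinarize_key,
    deinterleave,
    desymbolize,
    frame,
    interleave,
    make_interleaver,
    make_picklist,
    quantize_levels,
    symbolize,
    unframe,
)
from chemsteg.geometry import GridGeometry

API_KEY = "fa763032-6efb-4189-b626-9029686537b3"


class TestBinarize:
    def test_api_key_prefix_bits(self):
        bits = binarize_key(API_KEY)
        assert bits.size == 128
        # 'f' 'a' '7' '6' -> 1111 1010 0111 0110
        assert bits[:16].tolist() == [1, 1, 1, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 1, 1, 0]

    def test_zero_uuid_gives_zero_bits(self):
        bits = binarize_key("00000000-0000-0000-0000-000000000000")
        assert bits.size == 128 and not bits.any()

    def test_uuid_round_trip(self, rng):
        for _ in range(20):
            raw = rng.integers(0, 16, 32)
            key = "".join("0123456789abcdef"[v] for v in raw)
            key = f"{key[:8]}-{key[8:12]}-{key[12:16]}-{key[16:20]}-{key[20:]}"
            assert debinarize_key(binarize_key(key)) == key

    def test_bytes_mode_round_trip(self):
        assert debinarize_key(binarize_key("top secret", "bytes"), "bytes") == "top secret"

    def test_non_hex_rejected(self):
        with pytest.raises(ValueError):
            binarize_key("zz763032-6efb-4189-b626-9029686537b3")


class TestInterleaver:
    def test_worked_example(self):
        # the canonical 6-element example, quoted with 1-based indices
        idx = np.array([4, 3, 6, 1, 2, 5]) - 1
        out = interleave([0, 0, 0, 1, 1, 1], idx)
        assert out.tolist() == [1, 0, 1, 0, 0, 1]
        assert (np.argsort(idx) + 1).tolist() == [4, 5, 2, 1, 6, 3]
        assert deinterleave(out, idx).tolist() == [0, 0, 0, 1, 1, 1]

    def test_interleaving_breaks_runs(self):
        out = interleave([0, 0, 0, 1, 1, 1], np.array([4, 3, 6, 1, 2, 5]) - 1)
        runs = np.diff(np.where(np.diff(out) != 0)[0])
        longest = max(
            len(list(g))
            for g in np.split(out, np.where(np.diff(out) != 0)[0] + 1)
        )
        assert longest <= 2

    def test_single_element(self):
        assert make_interleaver(5, 1).tolist() == [0]

    def test_is_permutation_for_any_seed(self):
        for seed in (0, 1, 7919, 2**40):
            idx = make_interleaver(seed, 100)
            assert np.array_equal(np.sort(idx), np.arange(100))

    def test_adjacent_seeds_differ(self):
        assert not np.array_equal(make_interleaver(10, 6), make_interleaver(11, 6))

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            make_interleaver(1, 0)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            interleave([1, 2, 3], [0, 0, 2])

    def test_identity_permutation(self):
        seq = np.arange(9)
        assert np.array_equal(interleave(seq, np.arange(9)), seq)


class TestSymbols:
    def test_five_bit_symbol_example(self):
        # bits 11110 -> symbol 30, the level labelled "31/32"
        assert symbolize([1, 1, 1, 1, 0], 32).tolist() == [30]

    def test_binary_levels_are_identity(self, rng):
        bits = rng.integers(0, 2, 40)
        assert np.array_equal(symbolize(bits, 2), bits)

    @pytest.mark.parametrize("levels", [2, 4, 32])
    def test_round_trip(self, levels, rng):
        b = int(np.log2(levels))
        bits = rng.integers(0, 2, 10 * b).astype(np.uint8)
        assert np.array_equal(desymbolize(symbolize(bits, levels), levels), bits)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            symbolize([1, 0], 3)

    def test_quantization_rounds_ties_down(self):
        assert quantize_levels([30.4, 30.5, 30.6, -1.0, 40.0], 32).tolist() == [
            30,
            30,
            31,
            0,
            31,
        ]


class TestFrame:
    def test_six_repetitions_of_codeword_total_2304_raw_bits(self):
        plan = FramePlan.for_payload(384, n_extracts=6, levels=2, repetitions=6)
        assert plan.slot_bits - plan.pad_length == 2304

    def test_trivial_plan_is_interleaved_codeword(self, rng):
        bits = rng.integers(0, 2, 24).astype(np.uint8)
        plan = FramePlan.for_payload(24, n_extracts=1, levels=2, repetitions=1)
        mat = frame(bits, plan)
        idx = make_interleaver(plan.interleaver_seed, 24)
        assert np.array_equal(mat[0], interleave(bits, idx))

    @pytest.mark.parametrize("levels,reps", [(2, 1), (2, 6), (4, 1), (32, 1)])
    def test_frame_unframe_round_trip(self, levels, reps, rng):
        bits = rng.integers(0, 2, 96).astype(np.uint8)
        plan = FramePlan.for_payload(96, n_extracts=3, levels=levels, repetitions=reps)
        assert np.array_equal(unframe(frame(bits, plan), plan), bits)

    def test_over_capacity_reports_required_locations(self):
        plan = FramePlan(n_extracts=1, n_locations=4, levels=2)
        with pytest.raises(ValueError, match="n_locations >= 16"):
            frame(np.ones(16, np.uint8), plan)

    @pytest.mark.parametrize("levels,reps", [(2, 1), (2, 6), (4, 1), (32, 1)])
    def test_full_digital_round_trip(self, levels, reps, rng):
        """binarize -> turbo -> frame -> unframe -> turbo decode -> key."""
        cfg = TurboConfig()
        bits = binarize_key(API_KEY)
        cw = turbo_encode(bits, cfg)
        plan = FramePlan.for_payload(
            cw.size, n_extracts=4, levels=levels, repetitions=reps
        )
        recovered_cw = unframe(frame(cw, plan), plan)
        info = turbo_decode(bsc_llr(recovered_cw, 1e-3), cfg)
        assert debinarize_key(info) == API_KEY


class TestPicklist:
    def test_all_zero_matrix_gives_empty_picklist(self):
        pk = make_picklist(np.zeros((2, 4), int), GridGeometry(rows=2, cols=2))
        assert len(pk) == 0

    def test_single_transfer_default_volume(self):
        pk = make_picklist(np.array([[1]]), GridGeometry(rows=1, cols=1))
        assert len(pk) == 1
        assert pk.iloc[0].volume_nl == 2.5
        assert pk.iloc[0].level_index == 1

    def test_row_count_equals_nonzero_entries(self, rng):
        mat = rng.integers(0, 4, (3, 12))
        pk = make_picklist(mat, GridGeometry(rows=3, cols=4))
        assert len(pk) == int(np.count_nonzero(mat))

    def test_destination_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_picklist(np.ones((1, 5), int), GridGeometry(rows=2, cols=2))


class TestCapacity:
    def test_banknote_payload_limit(self):
        bits = capacity(2050, 60.0, 2.5, 1)
        assert bits == 49_200
        assert round(bits, -4) == 50_000  # the "about 50,000" statement

    def test_single_spot(self):
        assert capacity(1, 2.5, 2.5, 1) == 1

    def test_linear_in_bits_per_transfer(self):
        assert capacity(100, 60.0, 2.5, 2) == 2 * capacity(100, 60.0, 2.5, 1)

    def test_dispense_larger_than_spot_rejected(self):
        with pytest.raises(ValueError):
            capacity(10, 2.0, 2.5, 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_deinterleave_inverts_interleave(n, seed):
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 100, n)
    idx = make_interleaver(seed, n)
    assert np.array_equal(deinterleave(interleave(seq, idx), idx), seq)
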