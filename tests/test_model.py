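"""Core-model behavior: time-axis expansion, channel counting and
measurement-list resolution against an independent brute-force oracle."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snirfkit import (CrossReferenceError, DataBlock, GenSpec,
                      MeasurementListElement, SnirfIndexError,
                      StructuralError, channel_count, expand_time, generate,
                      resolve_channel)

from conftest import random_genspec


class TestExpandTime:
    @pytest.mark.parametrize("time, n_rows, expected", [
        ([0.0, 0.1], 5, [0.0, 0.1, 0.2, 0.3, 0.4]),
        ([0.0, 0.05, 0.2], 3, [0.0, 0.05, 0.2]),   # explicit: unchanged
        ([2.5, 0.125], 800, None),                 # checked via last element
    ])
    def test_expansion(self, time, n_rows, expected):
        out = expand_time(np.asarray(time), n_rows)
        assert out.shape == (n_rows,)
        if expected is not None:
            np.testing.assert_allclose(out, expected, rtol=0, atol=1e-12)
        else:
            # independent closed form: start + (n-1) * increment
            assert out[-1] == 2.5 + 799 * 0.125 == 102.375

    def test_length2_axis_for_two_rows_is_explicit(self):
        np.testing.assert_array_equal(expand_time(np.asarray([0.0, 0.1]), 2),
                                      [0.0, 0.1])

    def test_wrong_explicit_length_is_structural(self):
        with pytest.raises(StructuralError):
            expand_time(np.asarray([0.0, 0.1, 0.2]), 5)

    def test_non_increasing_explicit_axis_rejected(self):
        with pytest.raises(ValueError):
            expand_time(np.asarray([0.0, 0.2, 0.1]), 3)

    def test_nonpositive_increment_rejected(self):
        with pytest.raises(ValueError):
            expand_time(np.asarray([0.0, -0.1]), 5)

    @given(start=st.floats(-1e3, 1e3), inc=st.floats(1e-3, 10.0),
           n=st.integers(3, 500))
    @settings(derandomize=True, max_examples=60)
    def test_idempotent_on_own_output(self, start, inc, n):
        once = expand_time(np.asarray([start, inc]), n)
        np.testing.assert_array_equal(expand_time(once, n), once)


class TestChannelCount:
    def test_counts_columns(self):
        block = DataBlock(
            data_time_series=np.zeros((4, 7)),
            time=np.asarray([0.0, 0.1]),
            measurement_list=[
                MeasurementListElement(1, 1, 1) for _ in range(7)],
        )
        assert channel_count(block) == 7

    def test_empty_block_counts_zero(self):
        block = DataBlock(data_time_series=np.zeros((3, 0)),
                          time=np.asarray([0.0, 0.1]))
        assert channel_count(block) == 0

    def test_mismatch_is_structural(self):
        block = DataBlock(data_time_series=np.zeros((4, 3)),
                          time=np.asarray([0.0, 0.1]),
                          measurement_list=[MeasurementListElement(1, 1, 1)])
        with pytest.raises(StructuralError):
            channel_count(block)


def brute_force_table(element, block):
    """Oracle: materialize the entire resolved channel table at once by
    direct vectorized array indexing (no per-channel logic shared with
    resolve_channel)."""
    probe = element.probe
    spos = np.asarray(probe.source_pos_3d if probe.source_pos_3d is not None
                      else probe.source_pos_2d, dtype=float)
    dpos = np.asarray(probe.detector_pos_3d if probe.detector_pos_3d is not None
                      else probe.detector_pos_2d, dtype=float)
    wl = np.asarray(probe.wavelengths, dtype=float)
    src = np.asarray([m.source_index for m in block.measurement_list]) - 1
    det = np.asarray([m.detector_index for m in block.measurement_list]) - 1
    w = np.asarray([m.wavelength_index for m in block.measurement_list]) - 1
    return spos[src], dpos[det], wl[w]


class TestResolveChannel:
    def test_single_channel_file_resolves_to_sole_entries(self, minimal_model):
        desc = resolve_channel(minimal_model.nirs[0], 1, 1)
        assert desc.source_position == (0.0, 0.0, 0.0)
        assert desc.detector_position == (30.0, 0.0, 0.0)
        assert desc.wavelength == 760.0
        assert desc.column_index == 1

    def test_worked_example_channel_two(self, fig2_model):
        desc = resolve_channel(fig2_model.nirs[0], 1, 2)
        assert desc.source_position == (42.0, -125.0, 42.0)
        assert desc.wavelength == 830.0

    def test_prefers_3d_positions(self, fig2_model):
        # the fixture carries both layouts; 3-D must win
        assert len(resolve_channel(fig2_model.nirs[0], 1, 1).source_position) == 3

    @pytest.mark.parametrize("n_src, n_det, n_wl", [
        (1, 1, 1), (4, 4, 2), (16, 16, 3),
    ])
    def test_agrees_with_brute_force_oracle(self, n_src, n_det, n_wl):
        wls = (690.0, 750.0, 830.0)[:n_wl]
        model = generate(GenSpec(n_sources=n_src, n_detectors=n_det,
                                 wavelengths=wls, duration_s=0.5,
                                 sampling_rate_hz=10.0, seed=7))
        el = model.nirs[0]
        for b, block in enumerate(el.data, start=1):
            spos, dpos, wl = brute_force_table(el, block)
            for k in range(1, channel_count(block) + 1):
                desc = resolve_channel(el, b, k)
                np.testing.assert_array_equal(desc.source_position,
                                              spos[k - 1])
                np.testing.assert_array_equal(desc.detector_position,
                                              dpos[k - 1])
                assert desc.wavelength == wl[k - 1]
                assert desc.column_index == k

    def test_randomized_fixtures_match_oracle(self):
        rng = np.random.default_rng(2024)
        for i in range(10):
            model = generate(random_genspec(rng, seed=i))
            el = model.nirs[0]
            for b, block in enumerate(el.data, start=1):
                spos, dpos, wl = brute_force_table(el, block)
                for k in range(1, channel_count(block) + 1):
                    desc = resolve_channel(el, b, k)
                    np.testing.assert_array_equal(desc.source_position,
                                                  spos[k - 1])
                    assert desc.wavelength == wl[k - 1]

    def test_out_of_range_block_names_path(self, minimal_model):
        with pytest.raises(SnirfIndexError, match="data9"):
            resolve_channel(minimal_model.nirs[0], 9, 1)

    def test_out_of_range_channel_names_path(self, minimal_model):
        with pytest.raises(SnirfIndexError, match="measurementList5"):
            resolve_channel(minimal_model.nirs[0], 1, 5)

    def test_dangling_probe_index_is_cross_reference_error(self, minimal_model):
        el = minimal_model.nirs[0]
        el.data[0].measurement_list[0].wavelength_index = 3
        with pytest.raises(CrossReferenceError, match="wavelengthIndex"):
            resolve_channel(el, 1, 1)

    def test_resolution_does_not_mutate_inputs(self, fig2_model):
        snapshot = copy.deepcopy(fig2_model)
        resolve_channel(fig2_model.nirs[0], 1, 2)
        assert fig2_model == snapshot


def test_model_equality_detects_field_changes(fig2_model):
    other = copy.deepcopy(fig2_model)
    assert other == fig2_model
    other.nirs[0].data[0].data_time_series[0, 0] += 1.0
    assert other != fig2_model
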