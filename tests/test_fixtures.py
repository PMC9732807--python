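"""Generator properties: determinism, channel enumeration, per-block time
axes and the worked-example fixture's guaranteed content."""

import hashlib

import numpy as np
import pytest

from snirfkit import (GenSpec, build_corpus, expand_time, generate,
                      make_fig2_example, resolve_channel, validate,
                      write_snirf)


def _sha(path):
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


class TestGenerate:
    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        spec = GenSpec(seed=5)
        p1, p2 = str(tmp_path / "a.snirf"), str(tmp_path / "b.snirf")
        write_snirf(generate(spec), p1)
        write_snirf(generate(spec), p2)
        assert _sha(p1) == _sha(p2)

    def test_different_seed_different_content(self):
        a = generate(GenSpec(seed=1))
        b = generate(GenSpec(seed=2))
        assert a != b

    def test_channel_enumeration_source_major(self):
        model = generate(GenSpec(n_sources=1, n_detectors=1,
                                 wavelengths=(760.0, 850.0), duration_s=1.0))
        mlist = model.nirs[0].data[0].measurement_list
        assert len(mlist) == 2  # forced: 1 source x 1 detector x 2 wl
        assert [(m.source_index, m.detector_index, m.wavelength_index)
                for m in mlist] == [(1, 1, 1), (1, 1, 2)]

    def test_per_block_rates_and_onsets(self):
        model = generate(GenSpec(n_blocks=2, duration_s=2.0,
                                 sampling_rate_hz=(10.0, 50.0)))
        b1, b2 = model.nirs[0].data
        t1 = expand_time(b1.time, b1.n_rows)
        t2 = expand_time(b2.time, b2.n_rows)
        # increments are the reciprocals of the requested rates
        np.testing.assert_allclose(np.diff(t1), 0.1)
        np.testing.assert_allclose(np.diff(t2), 0.02)

    def test_generated_time_axes_strictly_increasing(self):
        model = generate(GenSpec(n_blocks=3, duration_s=1.0,
                                 sampling_rate_hz=(7.0, 13.0, 29.0),
                                 n_aux=2, seed=11))
        for block in model.nirs[0].data:
            assert np.all(np.diff(expand_time(block.time, block.n_rows)) > 0)
        for aux in model.nirs[0].aux:
            assert np.all(np.diff(expand_time(aux.time, aux.n_rows)) > 0)

    def test_all_generated_models_validate(self):
        for seed in range(5):
            assert validate(generate(GenSpec(seed=seed, n_stim=2,
                                             n_aux=1))).valid

    @pytest.mark.parametrize("bad", [
        dict(n_sources=0), dict(n_sources=33), dict(n_blocks=0),
        dict(duration_s=-1.0), dict(wavelengths=()),
        dict(wavelengths=(0.0,)), dict(sampling_rate_hz=(10.0, 20.0)),
    ])
    def test_caps_enforced(self, bad):
        with pytest.raises(ValueError):
            generate(GenSpec(**bad))


class TestFig2Fixture:
    def test_channel_two_resolution(self):
        model = make_fig2_example()
        desc = resolve_channel(model.nirs[0], 1, 2)
        assert desc.wavelength == 830.0
        assert desc.source_position == (42.0, -125.0, 42.0)

    def test_probe_content(self):
        probe = make_fig2_example().nirs[0].probe
        assert probe.wavelengths[1] == 830.0
        assert [42.0, -125.0, 42.0] in probe.source_pos_3d.tolist()

    def test_fixture_is_valid_and_deterministic(self):
        assert validate(make_fig2_example()).valid
        assert make_fig2_example() == make_fig2_example()


def test_build_corpus_layout(tmp_path):
    manifest = build_corpus(str(tmp_path), seed=0)
    for name in ("minimal", "fig2", "full"):
        assert (tmp_path / "valid" / f"{name}.snirf").exists()
    for defect, res in manifest.items():
        assert (tmp_path / "corrupted" / defect / "full.snirf").exists()
        assert res.code and res.location.startswith("/")
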