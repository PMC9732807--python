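"""Synthetic SNIRF fixtures: valid files at desk scale and a one-defect
corruptor, so every I/O path and validator rule can be exercised without
downloading any recording.

``generate`` emulates the structure of a multi-block continuous-wave
recording: optodes on a planar grid, channels enumerated over all
(source, detector, wavelength) triples, and per-channel signals built from a
baseline, slow sinusoidal physiology (cardiac- and respiration-band), white
Gaussian noise and stimulus-locked boxcar responses. Data blocks and
auxiliary signals carry independent sampling rates and onsets — the format
guarantees no shared clock. The physiology is deliberately schematic: the
container stores whatever the instrument produced, so fixtures only need
structural realism (see docs/methods.md for what this does and does not
emulate).

``corrupt`` takes a valid model, writes it, and seeds exactly one named
defect by direct HDF5 surgery, returning the path where the validator must
report it; the defect registry mirrors the validator's finding codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import h5py
import numpy as np

from .io import collection_names, write_snirf
from .model import (DATA_TYPE_CW_AMPLITUDE, AuxElement, DataBlock,
                    MeasurementListElement, MetaDataTags, NirsElement, Probe,
                    SnirfFile, StimElement)

__all__ = ["GenSpec", "generate", "make_minimal_example", "make_fig2_example",
           "corrupt", "CorruptResult", "DEFECTS", "default_corpus_spec",
           "build_corpus"]

_MAX_OPTODES = 32
_MAX_BLOCKS = 8
_MAX_DURATION_S = 600.0
_OPTODE_SPACING = 30.0  # mm, typical adult source-detector separation

_DEFAULT_TAGS = {
    "SubjectID": "sub-01",
    "MeasurementDate": "2024-01-15",
    "MeasurementTime": "09:30:00",
    "LengthUnit": "mm",
    "TimeUnit": "s",
    "FrequencyUnit": "Hz",
}


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one synthetic recording.

    ``sampling_rate_hz`` may be a single rate shared by all blocks or one
    rate per block; block onsets are independent. Counts are capped at
    desk scale (32 optodes, 8 blocks, 10 min) — fixtures exist to exercise
    structure, not to stress storage.
    """

    n_sources: int = 2
    n_detectors: int = 2
    wavelengths: tuple[float, ...] = (760.0, 850.0)
    n_blocks: int = 1
    duration_s: float = 5.0
    sampling_rate_hz: Union[float, tuple[float, ...]] = 10.0
    n_stim: int = 1
    n_aux: int = 1
    seed: int = 0

    def block_rates(self) -> list[float]:
        r = self.sampling_rate_hz
        if isinstance(r, (int, float)):
            return [float(r)] * self.n_blocks
        rates = [float(v) for v in r]
        if len(rates) != self.n_blocks:
            raise ValueError(
                f"got {len(rates)} sampling rates for {self.n_blocks} blocks")
        return rates

    def check(self) -> None:
        if not 1 <= self.n_sources <= _MAX_OPTODES:
            raise ValueError(f"n_sources must be 1..{_MAX_OPTODES}")
        if not 1 <= self.n_detectors <= _MAX_OPTODES:
            raise ValueError(f"n_detectors must be 1..{_MAX_OPTODES}")
        if not self.wavelengths or any(w <= 0 for w in self.wavelengths):
            raise ValueError("wavelengths must be non-empty and positive")
        if not 1 <= self.n_blocks <= _MAX_BLOCKS:
            raise ValueError(f"n_blocks must be 1..{_MAX_BLOCKS}")
        if not 0 < self.duration_s <= _MAX_DURATION_S:
            raise ValueError(f"duration_s must be in (0, {_MAX_DURATION_S}]")
        if any(r <= 0 for r in self.block_rates()):
            raise ValueError("sampling rates must be positive")
        if self.n_stim < 0 or self.n_aux < 0:
            raise ValueError("n_stim and n_aux must be >= 0")


def _grid_positions(n: int, z: float, offset: float) -> np.ndarray:
    """Optodes on a square grid in the z-plane, spaced at the standard
    source-detector separation; detectors are offset half a cell so that
    nearest source-detector pairs sit ~21 mm apart."""
    cols = max(1, math.ceil(math.sqrt(n)))
    pos = np.empty((n, 3), dtype=np.float64)
    for i in range(n):
        r, c = divmod(i, cols)
        pos[i] = (offset + c * _OPTODE_SPACING, offset + r * _OPTODE_SPACING, z)
    return pos


def _make_probe(spec: GenSpec) -> Probe:
    src3 = _grid_positions(spec.n_sources, z=0.0, offset=0.0)
    det3 = _grid_positions(spec.n_detectors, z=0.0,
                           offset=_OPTODE_SPACING / 2.0)
    return Probe(
        wavelengths=np.asarray(spec.wavelengths, dtype=np.float64),
        source_pos_2d=src3[:, :2].copy(),
        source_pos_3d=src3,
        detector_pos_2d=det3[:, :2].copy(),
        detector_pos_3d=det3,
        source_labels=[f"S{i}" for i in range(1, spec.n_sources + 1)],
        detector_labels=[f"D{i}" for i in range(1, spec.n_detectors + 1)],
    )


def _enumerate_channels(spec: GenSpec) -> list[MeasurementListElement]:
    # fixed source-major order: source, then detector, then wavelength
    return [
        MeasurementListElement(source_index=s, detector_index=d,
                               wavelength_index=w,
                               data_type=DATA_TYPE_CW_AMPLITUDE,
                               data_unit="V")
        for s in range(1, spec.n_sources + 1)
        for d in range(1, spec.n_detectors + 1)
        for w in range(1, len(spec.wavelengths) + 1)
    ]


def _make_stims(spec: GenSpec, rng: np.random.Generator) -> list[StimElement]:
    stims = []
    duration = min(5.0, spec.duration_s / 4.0)
    for j in range(spec.n_stim):
        onsets = np.sort(rng.uniform(0.0, spec.duration_s * 0.8, size=3))
        data = np.column_stack([onsets,
                                np.full(3, duration),
                                np.ones(3)])
        stims.append(StimElement(name=f"cond{chr(ord('A') + j)}", data=data))
    return stims


def _block_signal(t: np.ndarray, n_channels: int, stims: list[StimElement],
                  rng: np.random.Generator) -> np.ndarray:
    n = t.shape[0]
    out = np.empty((n, n_channels), dtype=np.float64)
    boxcar = np.zeros(n)
    for stim in stims:
        for onset, dur, amp in np.asarray(stim.data, dtype=np.float64):
            boxcar += amp * ((t >= onset) & (t < onset + dur))
    for c in range(n_channels):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out[:, c] = (
            1.0
            + 0.05 * np.sin(2.0 * np.pi * 1.1 * t + phase)   # cardiac band
            + 0.01 * np.sin(2.0 * np.pi * 0.25 * t + phase)  # respiration
            + 0.02 * boxcar                                  # evoked response
            + rng.normal(0.0, 0.005, size=n)
        )
    return out


def generate(spec: GenSpec) -> SnirfFile:
    """Build a seed-deterministic valid model from a :class:`GenSpec`.

    The first data block starts at t=0 with an explicit time axis; later
    blocks get random sub-second onsets and alternate between explicit and
    implicit ``[start, increment]`` axes so both encodings are exercised.
    Identical specs (including the seed) produce identical models and,
    after :func:`snirfkit.io.write_snirf`, byte-identical files.
    """
    spec.check()
    rng = np.random.default_rng(spec.seed)
    probe = _make_probe(spec)
    mlist_template = _enumerate_channels(spec)
    stims = _make_stims(spec, rng)

    blocks = []
    for j, rate in enumerate(spec.block_rates(), start=1):
        onset = 0.0 if j == 1 else float(rng.uniform(0.0, 0.5))
        n_samples = max(2, int(round(spec.duration_s * rate)))
        t = onset + np.arange(n_samples, dtype=np.float64) / rate
        data = _block_signal(t, len(mlist_template), stims, rng)
        explicit = (j % 2 == 1) or n_samples == 2
        time = t if explicit else np.asarray([onset, 1.0 / rate])
        mlist = [MeasurementListElement(
            source_index=m.source_index, detector_index=m.detector_index,
            wavelength_index=m.wavelength_index, data_type=m.data_type,
            data_unit=m.data_unit) for m in mlist_template]
        blocks.append(DataBlock(data_time_series=data, time=time,
                                measurement_list=mlist))

    auxes = []
    for j in range(1, spec.n_aux + 1):
        aux_rate = 25.0 * j
        aux_onset = float(rng.uniform(0.0, 0.5))
        n = max(2, int(round(spec.duration_s * aux_rate)))
        t = aux_onset + np.arange(n, dtype=np.float64) / aux_rate
        sig = 0.1 * np.sin(2.0 * np.pi * 0.5 * t) + rng.normal(0, 0.01, n)
        auxes.append(AuxElement(name=f"accel_{'xyz'[(j - 1) % 3]}",
                                data_time_series=sig,
                                time=np.asarray([aux_onset, 1.0 / aux_rate])))

    element = NirsElement(metadata=MetaDataTags(dict(_DEFAULT_TAGS)),
                          probe=probe, data=blocks, stim=stims, aux=auxes)
    return SnirfFile(format_version="1.0", nirs=[element])


def make_minimal_example() -> SnirfFile:
    """The smallest compliant file: one source, one detector, one
    wavelength, a 2-sample single-channel data block, the six required
    metadata tags — and nothing else."""
    probe = Probe(
        wavelengths=np.asarray([760.0]),
        source_pos_3d=np.asarray([[0.0, 0.0, 0.0]]),
        detector_pos_3d=np.asarray([[30.0, 0.0, 0.0]]),
    )
    block = DataBlock(
        data_time_series=np.asarray([[1.0], [1.1]]),
        time=np.asarray([0.0, 0.1]),
        measurement_list=[MeasurementListElement(
            source_index=1, detector_index=1, wavelength_index=1,
            data_type=DATA_TYPE_CW_AMPLITUDE)],
    )
    element = NirsElement(metadata=MetaDataTags(dict(_DEFAULT_TAGS)),
                          probe=probe, data=[block])
    return SnirfFile(format_version="1.0", nirs=[element])


def make_fig2_example() -> SnirfFile:
    """Deterministic worked example of measurement-list resolution.

    Channel 2 of the single data block is described by measurementList2
    with ``sourceIndex = 2`` and ``wavelengthIndex = 2``; the probe's
    sourcePos3D row 2 is ``[42.0, -125.0, 42.0]`` and wavelengths entry 2
    is 830 nm, so resolving block 1, channel 2 recovers exactly that
    optode coordinate and nominal wavelength.
    """
    rng = np.random.default_rng(42)
    probe = Probe(
        wavelengths=np.asarray([690.0, 830.0]),
        source_pos_3d=np.asarray([[-42.0, -125.0, 42.0],
                                  [42.0, -125.0, 42.0]]),
        source_pos_2d=np.asarray([[-42.0, -125.0], [42.0, -125.0]]),
        detector_pos_3d=np.asarray([[0.0, -110.0, 55.0]]),
        detector_pos_2d=np.asarray([[0.0, -110.0]]),
        source_labels=["S1", "S2"],
        detector_labels=["D1"],
    )
    # channel 2 is deliberately (source 2, wavelength 2); the rest fill in
    # the remaining source/wavelength combinations for the sole detector
    triples = [(1, 1, 1), (2, 1, 2), (1, 1, 2), (2, 1, 1)]
    mlist = [MeasurementListElement(source_index=s, detector_index=d,
                                    wavelength_index=w,
                                    data_type=DATA_TYPE_CW_AMPLITUDE,
                                    data_unit="V")
             for s, d, w in triples]
    n_samples = 10
    t = np.arange(n_samples) * 0.1
    data = 1.0 + 0.05 * np.sin(2 * np.pi * 1.1 * t)[:, None] \
        + rng.normal(0.0, 0.005, size=(n_samples, len(mlist)))
    block = DataBlock(data_time_series=data,
                      time=np.asarray([0.0, 0.1]),  # implicit uniform axis
                      measurement_list=mlist)
    stim = StimElement(name="tapping",
                       data=np.asarray([[0.2, 0.3, 1.0]]))
    element = NirsElement(metadata=MetaDataTags(dict(_DEFAULT_TAGS)),
                          probe=probe, data=[block], stim=[stim])
    return SnirfFile(format_version="1.0", nirs=[element])


# ---------------------------------------------------------------------------
# the corruptor
# ---------------------------------------------------------------------------

class CorruptResult(NamedTuple):
    path: str
    location: str  # where the validator must report the defect
    code: str      # the finding code it must use


#: Closed defect registry: defect name -> finding code the validator must
#: emit at the returned location.
DEFECTS: dict[str, str] = {
    "metadata_missing": "METADATA_MISSING",
    "wavelength_index_out_of_range": "INDEX_OUT_OF_RANGE",
    "measurement_list_truncated": "LIST_LENGTH_MISMATCH",
    "time_truncated": "TIME_LENGTH_MISMATCH",
    "time_nonmonotone": "TIME_NOT_INCREASING",
    "stim_renumbered": "NONCONTIGUOUS_INDEX",
    "zero_padded_name": "BAD_INDEX_NAME",
    "name_collision": "NAME_COLLISION",
    "probe_deleted": "REQUIRED_MISSING",
    "nirs_deleted": "REQUIRED_MISSING",
    "format_version_garbage": "VERSION_UNPARSEABLE",
    "processed_without_label": "DATA_TYPE_LABEL_MISSING",
    "unknown_data_type": "UNKNOWN_DATA_TYPE",
    "data_transposed": "LIST_LENGTH_MISMATCH",
}


def _rewrite(group: h5py.Group, name: str, data, dtype=None) -> None:
    if name in group:
        del group[name]
    group.create_dataset(name, data=data, dtype=dtype, track_times=False)


def corrupt(model: SnirfFile, defect: str, path: str,
            seed: int = 0) -> CorruptResult:
    """Write ``model`` to ``path`` and seed exactly one named defect by
    HDF5 surgery, leaving everything else untouched.

    Returns the written path, the HDF5 location at which the validator
    must report the defect, and the expected finding code. The ``seed``
    selects among equivalent targets (e.g. which channel's wavelengthIndex
    to break). Raises ``ValueError`` for unknown defect names or models
    too small to host the requested defect.
    """
    if defect not in DEFECTS:
        raise ValueError(f"unknown defect {defect!r}; "
                         f"known: {sorted(DEFECTS)}")
    code = DEFECTS[defect]
    rng = np.random.default_rng(seed)
    write_snirf(model, path)

    nirs_name = collection_names("nirs", len(model.nirs),
                                 bare_singleton=True)[0]
    nirs = f"/{nirs_name}"
    el = model.nirs[0]

    with h5py.File(path, "r+") as f:
        if defect == "metadata_missing":
            del f[f"{nirs}/metaDataTags/SubjectID"]
            return CorruptResult(path, f"{nirs}/metaDataTags", code)

        if defect == "wavelength_index_out_of_range":
            n_ch = len(el.data[0].measurement_list)
            n_wl = int(np.asarray(el.probe.wavelengths).size)
            k = int(rng.integers(1, n_ch + 1))
            ml = f"{nirs}/data1/measurementList{k}"
            _rewrite(f[ml], "wavelengthIndex", np.int32(n_wl + 1))
            return CorruptResult(path, f"{ml}/wavelengthIndex", code)

        if defect == "measurement_list_truncated":
            n_ch = len(el.data[0].measurement_list)
            if n_ch < 2:
                raise ValueError("need >= 2 channels to truncate the list")
            del f[f"{nirs}/data1/measurementList{n_ch}"]
            return CorruptResult(path, f"{nirs}/data1", code)

        if defect in ("time_truncated", "time_nonmonotone"):
            t = np.asarray(f[f"{nirs}/data1/time"][()], dtype=np.float64)
            if t.shape[0] < 5:
                raise ValueError("need an explicit time axis of >= 5 samples")
            if defect == "time_truncated":
                t = t[:-1]
            else:
                t[1], t[2] = t[2], t[1]
            _rewrite(f[f"{nirs}/data1"], "time", t)
            return CorruptResult(path, f"{nirs}/data1/time", code)

        if defect == "stim_renumbered":
            if len(el.stim) < 2:
                raise ValueError("need >= 2 stim elements to renumber")
            f.move(f"{nirs}/stim2", f"{nirs}/stim{len(el.stim) + 2}")
            return CorruptResult(path, f"{nirs}/stim", code)

        if defect == "zero_padded_name":
            if not el.stim:
                raise ValueError("need a stim element to zero-pad")
            f.move(f"{nirs}/stim1", f"{nirs}/stim01")
            return CorruptResult(path, f"{nirs}/stim01", code)

        if defect == "name_collision":
            if not el.stim:
                raise ValueError("need a stim element for a collision")
            g = f[nirs].create_group("stim")
            g.create_dataset("name", data="rogue",
                             dtype=h5py.string_dtype("utf-8"),
                             track_times=False)
            g.create_dataset("data", data=np.zeros((0, 3)), track_times=False)
            return CorruptResult(path, f"{nirs}/stim", code)

        if defect == "probe_deleted":
            del f[f"{nirs}/probe"]
            return CorruptResult(path, f"{nirs}/probe", code)

        if defect == "nirs_deleted":
            for name in list(f):
                if name != "formatVersion":
                    del f[name]
            return CorruptResult(path, "/", code)

        if defect == "format_version_garbage":
            _rewrite(f, "formatVersion", "not-a-version",
                     dtype=h5py.string_dtype("utf-8"))
            return CorruptResult(path, "/formatVersion", code)

        if defect == "processed_without_label":
            ml = f"{nirs}/data1/measurementList1"
            _rewrite(f[ml], "dataType", np.int32(99999))
            if "dataTypeLabel" in f[ml]:
                del f[ml]["dataTypeLabel"]
            return CorruptResult(path, ml, code)

        if defect == "unknown_data_type":
            ml = f"{nirs}/data1/measurementList1"
            _rewrite(f[ml], "dataType", np.int32(4242))
            return CorruptResult(path, f"{ml}/dataType", code)

        if defect == "data_transposed":
            dts = np.asarray(f[f"{nirs}/data1/dataTimeSeries"][()])
            if dts.shape[0] == dts.shape[1]:
                raise ValueError("square matrix: transposition undetectable")
            _rewrite(f[f"{nirs}/data1"], "dataTimeSeries",
                     np.ascontiguousarray(dts.T))
            return CorruptResult(path, f"{nirs}/data1", code)

    raise AssertionError(f"unhandled defect {defect!r}")  # pragma: no cover


def default_corpus_spec(seed: int = 0) -> GenSpec:
    """A spec rich enough to host every defect in :data:`DEFECTS`: two
    blocks at different rates, three stimulus conditions, one aux signal."""
    return GenSpec(n_sources=2, n_detectors=2, wavelengths=(760.0, 850.0),
                   n_blocks=2, duration_s=5.0, sampling_rate_hz=(10.0, 25.0),
                   n_stim=3, n_aux=1, seed=seed)


def build_corpus(root, seed: int = 0) -> dict[str, CorruptResult]:
    """Emit the full fixture corpus under ``root``: ``valid/`` holds the
    minimal, worked-example and generated files; ``corrupted/<defect>/``
    holds one single-defect file each. Returns the defect manifest."""
    import os

    valid_dir = os.path.join(root, "valid")
    os.makedirs(valid_dir, exist_ok=True)
    write_snirf(make_minimal_example(), os.path.join(valid_dir, "minimal.snirf"))
    write_snirf(make_fig2_example(), os.path.join(valid_dir, "fig2.snirf"))
    model = generate(default_corpus_spec(seed))
    write_snirf(model, os.path.join(valid_dir, "full.snirf"))

    manifest: dict[str, CorruptResult] = {}
    for defect in DEFECTS:
        d = os.path.join(root, "corrupted", defect)
        os.makedirs(d, exist_ok=True)
        manifest[defect] = corrupt(model, defect,
                                   os.path.join(d, "full.snirf"), seed=seed)
    return manifest
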