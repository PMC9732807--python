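"""In-memory model of a SNIRF file and the channel cross-reference logic.

A SNIRF file stores fNIRS recordings as a hierarchy: the root holds a format
version and one or more ``nirs`` elements; each element holds metadata tags,
a probe (optode geometry and nominal wavelengths) and one or more data blocks.
A data block is a time x channel matrix whose columns are described, one-to-one,
by a *measurement list* of 1-based indices into the probe arrays. Resolving a
channel means following sourceIndex/detectorIndex/wavelengthIndex from the
measurement-list element into the probe to recover positions and wavelength.

All indices exposed here are 1-based, matching the on-disk convention;
conversion to Python's 0-based indexing happens only at array-access
boundaries inside this module.

The dataclasses deliberately do **not** enforce invariants on construction:
damaged files read in permissive mode must be representable so the validator
can report on them. Use :func:`snirfkit.validator.validate` to check a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from .exceptions import CrossReferenceError, SnirfIndexError, StructuralError

__all__ = [
    "MetaDataTags",
    "Probe",
    "MeasurementListElement",
    "DataBlock",
    "StimElement",
    "AuxElement",
    "NirsElement",
    "SnirfFile",
    "ChannelDescription",
    "REQUIRED_METADATA_TAGS",
    "DATA_TYPE_CW_AMPLITUDE",
    "DATA_TYPE_PROCESSED",
    "KNOWN_DATA_TYPES",
    "resolve_channel",
    "channel_count",
    "expand_time",
]

#: Metadata tags every compliant file must carry (subject identifier,
#: acquisition date/time, and the measurement units).
REQUIRED_METADATA_TAGS = (
    "SubjectID",
    "MeasurementDate",
    "MeasurementTime",
    "LengthUnit",
    "TimeUnit",
    "FrequencyUnit",
)

#: Channel data-type registry. Continuous-wave raw amplitude is code 1;
#: code 99999 marks processed data and requires a dataTypeLabel. Other codes
#: (frequency-domain, time-domain, DCS) are accepted but reported as unknown.
DATA_TYPE_CW_AMPLITUDE = 1
DATA_TYPE_PROCESSED = 99999
KNOWN_DATA_TYPES = {DATA_TYPE_CW_AMPLITUDE, DATA_TYPE_PROCESSED}


def _arr_eq(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return np.array_equal(np.asarray(a), np.asarray(b))


def _extra_eq(a: dict, b: dict) -> bool:
    if set(a) != set(b):
        return False
    for k in a:
        va, vb = a[k], b[k]
        if isinstance(va, str) or isinstance(vb, str):
            if va != vb:
                return False
        elif not _arr_eq(va, vb):
            return False
    return True


@dataclass
class MetaDataTags:
    """Key/value descriptors attached to one ``nirs`` element.

    Six tags are mandatory (:data:`REQUIRED_METADATA_TAGS`); users may add
    any further string tags, which survive a read/write round trip untouched.
    """

    tags: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.tags[key]

    def __contains__(self, key: str) -> bool:
        return key in self.tags

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self.tags.get(key, default)

    def missing_required(self) -> list[str]:
        """Required tags that are absent or empty, in canonical order."""
        return [t for t in REQUIRED_METADATA_TAGS if not self.tags.get(t)]

    def __eq__(self, other):
        if not isinstance(other, MetaDataTags):
            return NotImplemented
        return self.tags == other.tags


@dataclass(eq=False)
class Probe:
    """Acquisition geometry: optode coordinates and nominal wavelengths.

    At least one of the 2-D/3-D position arrays must be present for sources
    and for detectors; when both are present their row counts must agree.
    Positions are expressed in the ``LengthUnit`` metadata tag.
    """

    wavelengths: np.ndarray  # (W,) nm, strictly positive
    source_pos_2d: Optional[np.ndarray] = None  # (S, 2)
    source_pos_3d: Optional[np.ndarray] = None  # (S, 3)
    detector_pos_2d: Optional[np.ndarray] = None  # (D, 2)
    detector_pos_3d: Optional[np.ndarray] = None  # (D, 3)
    source_labels: Optional[list[str]] = None
    detector_labels: Optional[list[str]] = None
    #: unrecognized datasets found inside /probe, preserved on round trip
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def n_sources(self) -> Optional[int]:
        for arr in (self.source_pos_3d, self.source_pos_2d):
            if arr is not None:
                return int(np.asarray(arr).shape[0])
        return None

    @property
    def n_detectors(self) -> Optional[int]:
        for arr in (self.detector_pos_3d, self.detector_pos_2d):
            if arr is not None:
                return int(np.asarray(arr).shape[0])
        return None

    def __eq__(self, other):
        if not isinstance(other, Probe):
            return NotImplemented
        return (
            _arr_eq(self.wavelengths, other.wavelengths)
            and _arr_eq(self.source_pos_2d, other.source_pos_2d)
            and _arr_eq(self.source_pos_3d, other.source_pos_3d)
            and _arr_eq(self.detector_pos_2d, other.detector_pos_2d)
            and _arr_eq(self.detector_pos_3d, other.detector_pos_3d)
            and self.source_labels == other.source_labels
            and self.detector_labels == other.detector_labels
            and _extra_eq(self.extra, other.extra)
        )


@dataclass(eq=False)
class MeasurementListElement:
    """Descriptor for one channel (one column of the data matrix).

    The three indices are 1-based references into the probe's source
    positions, detector positions and wavelengths arrays. ``data_type``
    follows the registry in :data:`KNOWN_DATA_TYPES`.
    """

    source_index: int
    detector_index: int
    wavelength_index: int
    data_type: int = DATA_TYPE_CW_AMPLITUDE
    data_type_label: Optional[str] = None
    data_unit: Optional[str] = None
    extra: dict[str, Any] = field(default_factory=dict)
    h5_name: Optional[str] = field(default=None, repr=False)

    def __eq__(self, other):
        if not isinstance(other, MeasurementListElement):
            return NotImplemented
        return (
            self.source_index == other.source_index
            and self.detector_index == other.detector_index
            and self.wavelength_index == other.wavelength_index
            and self.data_type == other.data_type
            and self.data_type_label == other.data_type_label
            and self.data_unit == other.data_unit
            and _extra_eq(self.extra, other.extra)
        )


@dataclass(eq=False)
class DataBlock:
    """One time x channel matrix plus its time axis and measurement list.

    ``time`` uses the dual SNIRF convention: either an explicit array of
    sample times (length = number of rows) or a length-2 ``[start,
    increment]`` pair describing a uniform axis (see :func:`expand_time`).
    Rows are time points; columns are channels, described in order by
    ``measurement_list``.
    """

    data_time_series: np.ndarray  # (T, C)
    time: np.ndarray  # (T,) explicit or (2,) implicit
    measurement_list: list[MeasurementListElement] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)
    h5_name: Optional[str] = field(default=None, repr=False)

    @property
    def n_rows(self) -> int:
        return int(np.asarray(self.data_time_series).shape[0])

    def expanded_time(self) -> np.ndarray:
        return expand_time(self.time, self.n_rows)

    def __eq__(self, other):
        if not isinstance(other, DataBlock):
            return NotImplemented
        return (
            _arr_eq(self.data_time_series, other.data_time_series)
            and _arr_eq(self.time, other.time)
            and self.measurement_list == other.measurement_list
            and _extra_eq(self.extra, other.extra)
        )


@dataclass(eq=False)
class StimElement:
    """Stimulus descriptor: a condition name and an events-by-3 array whose
    columns are [onset, duration, amplitude] in ``TimeUnit``. The column
    semantics follow common community usage; see docs/methods.md."""

    name: str
    data: np.ndarray  # (E, 3)
    extra: dict[str, Any] = field(default_factory=dict)
    h5_name: Optional[str] = field(default=None, repr=False)

    def __eq__(self, other):
        if not isinstance(other, StimElement):
            return NotImplemented
        return (self.name == other.name and _arr_eq(self.data, other.data)
                and _extra_eq(self.extra, other.extra))


@dataclass(eq=False)
class AuxElement:
    """Auxiliary signal (e.g. accelerometer) with its own time axis; aux
    signals may use sampling rates and onsets unrelated to the fNIRS data."""

    name: str
    data_time_series: np.ndarray  # (T,) or (T, K)
    time: np.ndarray  # same dual convention as DataBlock
    extra: dict[str, Any] = field(default_factory=dict)
    h5_name: Optional[str] = field(default=None, repr=False)

    @property
    def n_rows(self) -> int:
        return int(np.asarray(self.data_time_series).shape[0])

    def __eq__(self, other):
        if not isinstance(other, AuxElement):
            return NotImplemented
        return (self.name == other.name
                and _arr_eq(self.data_time_series, other.data_time_series)
                and _arr_eq(self.time, other.time)
                and _extra_eq(self.extra, other.extra))


@dataclass(eq=False)
class NirsElement:
    """One recording unit: metadata, probe and the indexed data/stim/aux
    collections. Distinct data blocks and aux signals may carry different
    sampling rates and onsets; no shared clock is assumed."""

    metadata: MetaDataTags
    probe: Probe
    data: list[DataBlock] = field(default_factory=list)
    stim: list[StimElement] = field(default_factory=list)
    aux: list[AuxElement] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)
    h5_name: Optional[str] = field(default=None, repr=False)

    def __eq__(self, other):
        if not isinstance(other, NirsElement):
            return NotImplemented
        return (
            self.metadata == other.metadata
            and self.probe == other.probe
            and self.data == other.data
            and self.stim == other.stim
            and self.aux == other.aux
            and _extra_eq(self.extra, other.extra)
        )


@dataclass(eq=False)
class SnirfFile:
    """Root container: a semantic-version string plus one or more ``nirs``
    elements (1-based indexed collection, stored here as a Python list where
    list position k-1 holds element k)."""

    format_version: str = "1.0"
    nirs: list[NirsElement] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, SnirfFile):
            return NotImplemented
        return (self.format_version == other.format_version
                and self.nirs == other.nirs
                and _extra_eq(self.extra, other.extra))


@dataclass(frozen=True)
class ChannelDescription:
    """Fully resolved view of one channel: where its light came from and
    went to, at which nominal wavelength, and which column it occupies."""

    source_position: tuple[float, ...]
    detector_position: tuple[float, ...]
    wavelength: float
    data_type: int
    column_index: int  # 1-based


def expand_time(time: Sequence[float], n_rows: int) -> np.ndarray:
    """Materialize a time axis for a block with ``n_rows`` samples.

    Explicit axes (length ``n_rows``) are returned unchanged after a
    strict-monotonicity check. The implicit length-2 form ``[start,
    increment]`` expands to ``start + k*increment`` for ``k = 0..n_rows-1``.
    A length-2 array for a 2-row block is taken as explicit.

    Raises
    ------
    StructuralError
        if the explicit array length does not match ``n_rows``.
    ValueError
        if an explicit axis is not strictly increasing, or an implicit
        increment is not positive.
    """
    t = np.asarray(time, dtype=np.float64)
    if t.ndim != 1:
        raise StructuralError(f"time axis must be 1-D, got shape {t.shape}")
    if t.shape[0] == 2 and n_rows != 2:
        start, inc = float(t[0]), float(t[1])
        if inc <= 0:
            raise ValueError(f"implicit time increment must be > 0, got {inc}")
        return start + inc * np.arange(n_rows, dtype=np.float64)
    if t.shape[0] != n_rows:
        raise StructuralError(
            f"explicit time axis has {t.shape[0]} entries for {n_rows} rows")
    if n_rows > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("explicit time axis is not strictly increasing")
    return t


def channel_count(block: DataBlock) -> int:
    """Number of channels (columns) in a block.

    Raises :class:`StructuralError` when the measurement-list length
    disagrees with the column count — the validator reuses this rule.
    """
    arr = np.asarray(block.data_time_series)
    if arr.ndim != 2:
        raise StructuralError(
            f"dataTimeSeries must be 2-D, got shape {arr.shape}")
    n_cols = int(arr.shape[1])
    if n_cols != len(block.measurement_list):
        raise StructuralError(
            f"dataTimeSeries has {n_cols} columns but measurement list "
            f"has {len(block.measurement_list)} elements")
    return n_cols


def _lookup_position(pos3d, pos2d, index_1b: int, what: str,
                     path: str) -> tuple[float, ...]:
    # 3-D coordinates win when a probe carries both layouts
    arr = pos3d if pos3d is not None else pos2d
    if arr is None:
        raise CrossReferenceError(f"probe has no {what} position arrays "
                                  f"(needed by {path})")
    arr = np.asarray(arr, dtype=np.float64)
    if not 1 <= index_1b <= arr.shape[0]:
        raise CrossReferenceError(
            f"{path} = {index_1b} is outside the probe's {what} array "
            f"of length {arr.shape[0]}")
    return tuple(float(v) for v in arr[index_1b - 1])


def resolve_channel(element: NirsElement, block_index: int,
                    channel_index: int) -> ChannelDescription:
    """Follow a channel's measurement-list indices into the probe.

    ``block_index`` and ``channel_index`` are 1-based, matching the on-disk
    group names (``data1``, ``measurementList2``, ...). Returns the source
    and detector positions (3-D preferred when both layouts exist), the
    nominal wavelength in nm, the data-type code and the channel's column.

    Raises
    ------
    SnirfIndexError
        block or channel index outside its collection; the message names
        the offending path.
    CrossReferenceError
        a measurement-list index dangles outside the probe arrays.
    """
    if not 1 <= block_index <= len(element.data):
        raise SnirfIndexError(
            f"data{block_index}: block index out of range "
            f"(file has {len(element.data)} data blocks)")
    block = element.data[block_index - 1]
    n_ch = channel_count(block)
    if not 1 <= channel_index <= n_ch:
        raise SnirfIndexError(
            f"data{block_index}/measurementList{channel_index}: channel "
            f"index out of range (block has {n_ch} channels)")
    ml = block.measurement_list[channel_index - 1]
    probe = element.probe
    base = f"data{block_index}/measurementList{channel_index}"

    source_position = _lookup_position(
        probe.source_pos_3d, probe.source_pos_2d, ml.source_index,
        "source", f"{base}/sourceIndex")
    detector_position = _lookup_position(
        probe.detector_pos_3d, probe.detector_pos_2d, ml.detector_index,
        "detector", f"{base}/detectorIndex")

    wl = np.asarray(probe.wavelengths, dtype=np.float64)
    if not 1 <= ml.wavelength_index <= wl.shape[0]:
        raise CrossReferenceError(
            f"{base}/wavelengthIndex = {ml.wavelength_index} is outside "
            f"the probe's wavelengths array of length {wl.shape[0]}")

    return ChannelDescription(
        source_position=source_position,
        detector_position=detector_position,
        wavelength=float(wl[ml.wavelength_index - 1]),
        data_type=int(ml.data_type),
        column_index=channel_index,
    )
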