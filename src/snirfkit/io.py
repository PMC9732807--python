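"""Bidirectional HDF5 serialization for the SNIRF container.

The on-disk hierarchy is::

    /formatVersion
    /nirs{i}/metaDataTags/*
    /nirs{i}/probe/{wavelengths, sourcePos2D, sourcePos3D,
                    detectorPos2D, detectorPos3D, sourceLabels, detectorLabels}
    /nirs{i}/data{j}/{dataTimeSeries, time,
                      measurementList{k}/{sourceIndex, detectorIndex,
                      wavelengthIndex, dataType, dataTypeLabel, dataUnit}}
    /nirs{i}/stim{j}/{name, data}
    /nirs{i}/aux{j}/{name, dataTimeSeries, time}

Repeatable groups use the *indexed group* convention: a collection shares a
base name with 1-based, zero-padding-free decimal suffixes (stim1, stim2,
stim3). A bare base name is legal only as the sole member of its collection.
This writer emits a bare ``nirs`` for singleton recordings and always-indexed
``data1``/``measurementList1``/``stim1``/``aux1`` groups; the reader accepts
both dialects, plus fixed-length byte strings and any numeric width, for
interoperability with vendor exports.

Reading can run in *permissive* mode (used by the validator), in which
structural and naming violations are collected as findings instead of raised,
so damaged files can still be reported on.
"""

from __future__ import annotations

import os
from typing import Any, Optional

import h5py
import numpy as np

from .exceptions import (FormatError, NamingError, StructuralError,
                         ValidationError)
from .model import (AuxElement, DataBlock, MeasurementListElement,
                    MetaDataTags, NirsElement, Probe, SnirfFile, StimElement)

__all__ = [
    "parse_indexed_name",
    "render_indexed_name",
    "collection_names",
    "read_snirf",
    "read_snirf_permissive",
    "write_snirf",
    "DEFAULT_FORMAT_VERSION",
]

DEFAULT_FORMAT_VERSION = "1.0"

_STR_DTYPE = h5py.string_dtype(encoding="utf-8")
_DIGITS = "0123456789"


# ---------------------------------------------------------------------------
# indexed-group names
# ---------------------------------------------------------------------------

def parse_indexed_name(name: str) -> tuple[str, Optional[int]]:
    """Split an indexed-group name into (base, index).

    The maximal trailing run of ASCII digits is the index; a name with no
    trailing digits is a bare base (index ``None``). Indices start at 1 and
    are written without zero-padding, so ``stim0`` and ``stim01`` are
    malformed.

    >>> parse_indexed_name("stim3")
    ('stim', 3)
    >>> parse_indexed_name("probe")
    ('probe', None)
    """
    if not name:
        raise NamingError("empty group name")
    i = len(name)
    while i > 0 and name[i - 1] in _DIGITS:
        i -= 1
    base, digits = name[:i], name[i:]
    if not digits:
        return base, None
    if digits[0] == "0":
        raise NamingError(
            f"'{name}': indexed-group indices start at 1 and must not be "
            f"zero-padded")
    return base, int(digits)


def render_indexed_name(base: str, index: Optional[int]) -> str:
    """Inverse of :func:`parse_indexed_name` on legal (base, index) pairs."""
    if not base:
        raise NamingError("empty base name")
    if base[-1] in _DIGITS:
        raise NamingError(f"base '{base}' must not end in a digit")
    if index is None:
        return base
    if not isinstance(index, (int, np.integer)) or index < 1:
        raise NamingError(f"index must be a positive integer, got {index!r}")
    return f"{base}{int(index)}"


def collection_names(base: str, n: int, bare_singleton: bool = False) -> list[str]:
    """Group names for an n-element collection (``stim1``..``stimN``); a
    singleton may be written with the bare base name."""
    if n == 1 and bare_singleton:
        return [base]
    return [render_indexed_name(base, i) for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# low-level dataset helpers
# ---------------------------------------------------------------------------

def _wds(group: h5py.Group, name: str, data, dtype=None) -> None:
    # track_times=False keeps writes byte-deterministic
    group.create_dataset(name, data=data, dtype=dtype, track_times=False)


def _write_string(group: h5py.Group, name: str, value: str) -> None:
    _wds(group, name, value, dtype=_STR_DTYPE)


def _write_float_array(group: h5py.Group, name: str, value) -> None:
    _wds(group, name, np.asarray(value, dtype=np.float64))


def _write_int(group: h5py.Group, name: str, value: int) -> None:
    _wds(group, name, np.int32(value))


def _decode(value) -> Any:
    """Decode an h5py scalar read: bytes -> str (UTF-8), numpy scalar kept."""
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return value


def _read_scalar(ds: h5py.Dataset) -> Any:
    value = ds[()]
    if isinstance(value, np.ndarray):
        # tolerate 1-element arrays where a scalar is expected
        if value.size == 1:
            value = value.reshape(())[()]
        else:
            return value
    return _decode(value)


def _read_string(ds: h5py.Dataset) -> str:
    value = _read_scalar(ds)
    if isinstance(value, np.ndarray):
        raise StructuralError(f"{ds.name}: expected a string scalar")
    return str(value)


def _read_int(ds: h5py.Dataset) -> int:
    value = _read_scalar(ds)
    return int(value)


def _read_float_array(ds: h5py.Dataset) -> np.ndarray:
    return np.asarray(ds[()], dtype=np.float64)


def _read_string_list(ds: h5py.Dataset) -> list[str]:
    raw = np.asarray(ds[()]).ravel()
    return [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in raw]


def _read_any(ds: h5py.Dataset) -> Any:
    """Read an unrecognized dataset for the preservation area."""
    value = ds[()]
    if isinstance(value, np.ndarray):
        if value.dtype.kind in ("O", "S"):
            return np.asarray([_decode(v) for v in value.ravel()],
                              dtype=object).reshape(value.shape)
        return value
    return _decode(value)


def _write_any(group: h5py.Group, name: str, value) -> None:
    if isinstance(value, str):
        _write_string(group, name, value)
    elif isinstance(value, np.ndarray) and value.dtype.kind == "O":
        _wds(group, name, value.astype(_STR_DTYPE), dtype=_STR_DTYPE)
    else:
        _wds(group, name, np.asarray(value))


# ---------------------------------------------------------------------------
# permissive-read bookkeeping
# ---------------------------------------------------------------------------

class ReadIssue:
    """A structural/naming problem found while reading; consumed by the
    validator, which converts it into a report finding."""

    def __init__(self, code: str, location: str, message: str):
        self.code = code
        self.location = location
        self.message = message

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"ReadIssue({self.code}, {self.location}, {self.message!r})"


class _Ctx:
    """Collects issues in permissive mode, raises immediately otherwise."""

    def __init__(self, permissive: bool):
        self.permissive = permissive
        self.issues: list[ReadIssue] = []

    def issue(self, code: str, location: str, message: str,
              exc_type=StructuralError) -> None:
        if self.permissive:
            self.issues.append(ReadIssue(code, location, message))
        else:
            raise exc_type(f"{location}: {message}")


def _indexed_members(group: h5py.Group, base: str, loc: str,
                     ctx: _Ctx) -> list[tuple[Optional[int], str]]:
    """Collect, order and vet the members of one indexed collection.

    Returns (index, name) pairs sorted by numeric index (bare member first).
    Emits naming issues for zero-padded indices, bare+indexed collisions and
    non-contiguous index sets; reading continues past all of them in
    permissive mode.
    """
    members: list[tuple[Optional[int], str]] = []
    for name in group:
        i = len(name)
        while i > 0 and name[i - 1] in _DIGITS:
            i -= 1
        if name[:i] != base:
            continue
        digits = name[i:]
        if not digits:
            members.append((None, name))
            continue
        if digits[0] == "0":
            ctx.issue("BAD_INDEX_NAME", f"{loc}/{name}",
                      f"indexed-group index '{digits}' is zero-padded or "
                      f"zero; indices start at 1 with no padding",
                      NamingError)
            continue
        members.append((int(digits), name))

    bare = [m for m in members if m[0] is None]
    indexed = sorted((m for m in members if m[0] is not None),
                     key=lambda m: m[0])
    if bare and indexed:
        ctx.issue("NAME_COLLISION", f"{loc}/{base}",
                  f"bare group '{base}' coexists with indexed "
                  f"'{base}1'-style siblings", NamingError)
    if indexed:
        indices = [m[0] for m in indexed]
        if indices != list(range(1, len(indices) + 1)):
            ctx.issue("NONCONTIGUOUS_INDEX", f"{loc}/{base}",
                      f"'{base}' collection indices {indices} are not "
                      f"contiguous starting at 1")
    return bare + indexed


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_metadata(group: h5py.Group) -> MetaDataTags:
    tags: dict[str, str] = {}
    for name, item in group.items():
        if isinstance(item, h5py.Dataset):
            tags[name] = _read_string(item)
    return MetaDataTags(tags=tags)


_PROBE_FIELDS = {
    "wavelengths": ("wavelengths", _read_float_array),
    "sourcePos2D": ("source_pos_2d", _read_float_array),
    "sourcePos3D": ("source_pos_3d", _read_float_array),
    "detectorPos2D": ("detector_pos_2d", _read_float_array),
    "detectorPos3D": ("detector_pos_3d", _read_float_array),
    "sourceLabels": ("source_labels", _read_string_list),
    "detectorLabels": ("detector_labels", _read_string_list),
}


def _read_probe(group: h5py.Group, loc: str, ctx: _Ctx) -> Probe:
    kwargs: dict[str, Any] = {"wavelengths": np.empty(0, dtype=np.float64)}
    extra: dict[str, Any] = {}
    for name, item in group.items():
        if name in _PROBE_FIELDS and isinstance(item, h5py.Dataset):
            attr, reader = _PROBE_FIELDS[name]
            kwargs[attr] = reader(item)
        elif isinstance(item, h5py.Dataset):
            extra[name] = _read_any(item)
    # a missing wavelengths array is the validator's finding, not a read error
    return Probe(extra=extra, **kwargs)


def _read_measurement_list_element(group: h5py.Group, loc: str,
                                   ctx: _Ctx) -> MeasurementListElement:
    def geti(name: str, default: int = 0) -> int:
        if name in group:
            return _read_int(group[name])
        ctx.issue("REQUIRED_MISSING", f"{loc}/{name}",
                  f"measurement-list element is missing '{name}'")
        return default

    known = {"sourceIndex", "detectorIndex", "wavelengthIndex", "dataType",
             "dataTypeLabel", "dataUnit"}
    extra = {name: _read_any(item) for name, item in group.items()
             if name not in known and isinstance(item, h5py.Dataset)}
    return MeasurementListElement(
        source_index=geti("sourceIndex"),
        detector_index=geti("detectorIndex"),
        wavelength_index=geti("wavelengthIndex"),
        data_type=geti("dataType", default=0),
        data_type_label=(_read_string(group["dataTypeLabel"])
                         if "dataTypeLabel" in group else None),
        data_unit=(_read_string(group["dataUnit"])
                   if "dataUnit" in group else None),
        extra=extra,
        h5_name=group.name.rsplit("/", 1)[-1],
    )


def _read_data_block(group: h5py.Group, loc: str, ctx: _Ctx) -> DataBlock:
    if "dataTimeSeries" in group:
        dts = _read_float_array(group["dataTimeSeries"])
        if dts.ndim == 1:  # vendor dialect: single channel stored flat
            dts = dts.reshape(-1, 1)
    else:
        ctx.issue("REQUIRED_MISSING", f"{loc}/dataTimeSeries",
                  "data block is missing dataTimeSeries")
        dts = np.empty((0, 0), dtype=np.float64)
    if "time" in group:
        time = _read_float_array(group["time"]).ravel()
    else:
        ctx.issue("REQUIRED_MISSING", f"{loc}/time",
                  "data block is missing the time axis")
        time = np.empty(0, dtype=np.float64)

    mlist = [
        _read_measurement_list_element(group[name], f"{loc}/{name}", ctx)
        for _, name in _indexed_members(group, "measurementList", loc, ctx)
        if isinstance(group[name], h5py.Group)
    ]
    known_prefixes = ("dataTimeSeries", "time")
    extra = {}
    for name, item in group.items():
        if name in known_prefixes or name.startswith("measurementList"):
            continue
        if isinstance(item, h5py.Dataset):
            extra[name] = _read_any(item)
    return DataBlock(data_time_series=dts, time=time, measurement_list=mlist,
                     extra=extra, h5_name=group.name.rsplit("/", 1)[-1])


def _read_stim(group: h5py.Group, loc: str, ctx: _Ctx) -> StimElement:
    name = _read_string(group["name"]) if "name" in group else ""
    if "name" not in group:
        ctx.issue("REQUIRED_MISSING", f"{loc}/name",
                  "stim element is missing its name")
    if "data" in group:
        data = _read_float_array(group["data"])
        if data.ndim == 1 and data.size in (0, 3):
            data = data.reshape(-1, 3)
    else:
        data = np.empty((0, 3), dtype=np.float64)
    extra = {n: _read_any(it) for n, it in group.items()
             if n not in ("name", "data") and isinstance(it, h5py.Dataset)}
    return StimElement(name=name, data=data, extra=extra,
                       h5_name=group.name.rsplit("/", 1)[-1])


def _read_aux(group: h5py.Group, loc: str, ctx: _Ctx) -> AuxElement:
    name = _read_string(group["name"]) if "name" in group else ""
    if "name" not in group:
        ctx.issue("REQUIRED_MISSING", f"{loc}/name",
                  "aux element is missing its name")
    dts = (_read_float_array(group["dataTimeSeries"])
           if "dataTimeSeries" in group else np.empty(0, dtype=np.float64))
    time = (_read_float_array(group["time"]).ravel()
            if "time" in group else np.empty(0, dtype=np.float64))
    extra = {n: _read_any(it) for n, it in group.items()
             if n not in ("name", "dataTimeSeries", "time")
             and isinstance(it, h5py.Dataset)}
    return AuxElement(name=name, data_time_series=dts, time=time, extra=extra,
                      h5_name=group.name.rsplit("/", 1)[-1])


def _read_nirs(group: h5py.Group, loc: str, ctx: _Ctx) -> NirsElement:
    if "metaDataTags" in group and isinstance(group["metaDataTags"], h5py.Group):
        metadata = _read_metadata(group["metaDataTags"])
    else:
        ctx.issue("REQUIRED_MISSING", f"{loc}/metaDataTags",
                  "nirs element is missing the metaDataTags group")
        metadata = MetaDataTags()
    if "probe" in group and isinstance(group["probe"], h5py.Group):
        probe = _read_probe(group["probe"], f"{loc}/probe", ctx)
    else:
        ctx.issue("REQUIRED_MISSING", f"{loc}/probe",
                  "nirs element is missing the probe group")
        probe = Probe(wavelengths=np.empty(0, dtype=np.float64))

    data = [_read_data_block(group[name], f"{loc}/{name}", ctx)
            for _, name in _indexed_members(group, "data", loc, ctx)
            if isinstance(group[name], h5py.Group)]
    stim = [_read_stim(group[name], f"{loc}/{name}", ctx)
            for _, name in _indexed_members(group, "stim", loc, ctx)
            if isinstance(group[name], h5py.Group)]
    aux = [_read_aux(group[name], f"{loc}/{name}", ctx)
           for _, name in _indexed_members(group, "aux", loc, ctx)
           if isinstance(group[name], h5py.Group)]

    extra = {}
    for name, item in group.items():
        if name in ("metaDataTags", "probe"):
            continue
        base, _ = _safe_parse(name)
        if base in ("data", "stim", "aux", "measurementList"):
            continue
        if isinstance(item, h5py.Dataset):
            extra[name] = _read_any(item)
    return NirsElement(metadata=metadata, probe=probe, data=data, stim=stim,
                       aux=aux, extra=extra,
                       h5_name=group.name.rsplit("/", 1)[-1])


def _safe_parse(name: str) -> tuple[str, Optional[int]]:
    i = len(name)
    while i > 0 and name[i - 1] in _DIGITS:
        i -= 1
    return name[:i], None


def _read_file(f: h5py.File, ctx: _Ctx) -> SnirfFile:
    if "formatVersion" in f:
        format_version = _read_string(f["formatVersion"])
    else:
        ctx.issue("REQUIRED_MISSING", "/formatVersion",
                  "file is missing the /formatVersion dataset")
        format_version = ""

    nirs = [_read_nirs(f[name], f"/{name}", ctx)
            for _, name in _indexed_members(f, "nirs", "", ctx)
            if isinstance(f[name], h5py.Group)]
    if not nirs:
        ctx.issue("REQUIRED_MISSING", "/",
                  "file contains no nirs groups")
    extra = {}
    for name, item in f.items():
        if name == "formatVersion" or _safe_parse(name)[0] == "nirs":
            continue
        if isinstance(item, h5py.Dataset):
            extra[name] = _read_any(item)
    return SnirfFile(format_version=format_version, nirs=nirs, extra=extra)


def _open(path) -> h5py.File:
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file")
    try:
        return h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path}: not an HDF5 container ({exc})") from exc


def read_snirf(path) -> SnirfFile:
    """Read a ``.snirf`` file into the in-memory model.

    Indexed collections are returned sorted by numeric index regardless of
    HDF5 iteration order; strings are decoded as UTF-8 whether stored as
    variable- or fixed-length; any numeric width is accepted. Unrecognized
    datasets inside recognized groups are retained in each object's
    ``extra`` preservation area and written back by :func:`write_snirf`.

    Raises :class:`FormatError` for non-HDF5 input, :class:`NamingError`
    for malformed or colliding indexed names, and :class:`StructuralError`
    for missing required structure (e.g. /formatVersion).
    """
    ctx = _Ctx(permissive=False)
    with _open(path) as f:
        return _read_file(f, ctx)


def read_snirf_permissive(path) -> tuple[SnirfFile, list[ReadIssue]]:
    """Like :func:`read_snirf`, but collects structural/naming problems as
    :class:`ReadIssue` records instead of raising, so the validator can
    report on damaged files. Non-HDF5 input still raises FormatError."""
    ctx = _Ctx(permissive=True)
    with _open(path) as f:
        model = _read_file(f, ctx)
    return model, ctx.issues


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _write_probe(group: h5py.Group, probe: Probe) -> None:
    _write_float_array(group, "wavelengths", probe.wavelengths)
    for name, value in (("sourcePos2D", probe.source_pos_2d),
                        ("sourcePos3D", probe.source_pos_3d),
                        ("detectorPos2D", probe.detector_pos_2d),
                        ("detectorPos3D", probe.detector_pos_3d)):
        if value is not None:
            _write_float_array(group, name, value)
    for name, labels in (("sourceLabels", probe.source_labels),
                         ("detectorLabels", probe.detector_labels)):
        if labels is not None:
            _wds(group, name, np.asarray(labels, dtype=object),
                 dtype=_STR_DTYPE)
    for name, value in probe.extra.items():
        _write_any(group, name, value)


def _write_measurement_list_element(group: h5py.Group,
                                    ml: MeasurementListElement) -> None:
    _write_int(group, "sourceIndex", ml.source_index)
    _write_int(group, "detectorIndex", ml.detector_index)
    _write_int(group, "wavelengthIndex", ml.wavelength_index)
    _write_int(group, "dataType", ml.data_type)
    if ml.data_type_label is not None:
        _write_string(group, "dataTypeLabel", ml.data_type_label)
    if ml.data_unit is not None:
        _write_string(group, "dataUnit", ml.data_unit)
    for name, value in ml.extra.items():
        _write_any(group, name, value)


def _write_data_block(group: h5py.Group, block: DataBlock) -> None:
    dts = np.asarray(block.data_time_series, dtype=np.float64)
    _wds(group, "dataTimeSeries", dts)
    _write_float_array(group, "time", block.time)
    names = collection_names("measurementList", len(block.measurement_list))
    for name, ml in zip(names, block.measurement_list):
        _write_measurement_list_element(group.create_group(name), ml)
    for name, value in block.extra.items():
        _write_any(group, name, value)


def _write_stim(group: h5py.Group, stim: StimElement) -> None:
    _write_string(group, "name", stim.name)
    _wds(group, "data", np.asarray(stim.data, dtype=np.float64))
    for name, value in stim.extra.items():
        _write_any(group, name, value)


def _write_aux(group: h5py.Group, aux: AuxElement) -> None:
    _write_string(group, "name", aux.name)
    _wds(group, "dataTimeSeries",
         np.asarray(aux.data_time_series, dtype=np.float64))
    _write_float_array(group, "time", aux.time)
    for name, value in aux.extra.items():
        _write_any(group, name, value)


def _write_nirs(group: h5py.Group, el: NirsElement) -> None:
    tags_group = group.create_group("metaDataTags")
    for key, value in el.metadata.tags.items():
        _write_string(tags_group, key, value)
    _write_probe(group.create_group("probe"), el.probe)
    for name, block in zip(collection_names("data", len(el.data)), el.data):
        _write_data_block(group.create_group(name), block)
    for name, stim in zip(collection_names("stim", len(el.stim)), el.stim):
        _write_stim(group.create_group(name), stim)
    for name, aux in zip(collection_names("aux", len(el.aux)), el.aux):
        _write_aux(group.create_group(name), aux)
    for name, value in el.extra.items():
        _write_any(group, name, value)


def write_snirf(model: SnirfFile, path, force: bool = False) -> None:
    """Serialize a model to an HDF5 ``.snirf`` file.

    The writer refuses models with ERROR-level compliance findings unless
    ``force`` is set (raising :class:`ValidationError` with the report).
    Floating-point data are stored as 64-bit, index fields as 32-bit signed
    integers, strings as variable-length UTF-8; ``read_snirf(write_snirf(m))``
    reproduces ``m`` exactly, including unknown preserved content.
    """
    if not force:
        from .validator import validate  # local import: validator reads files

        report = validate(model)
        if not report.valid:
            raise ValidationError(report)
    with h5py.File(path, "w") as f:
        _write_string(f, "formatVersion",
                      model.format_version or DEFAULT_FORMAT_VERSION)
        names = collection_names("nirs", len(model.nirs), bare_singleton=True)
        for name, el in zip(names, model.nirs):
            _write_nirs(f.create_group(name), el)
        for name, value in model.extra.items():
            _write_any(f, name, value)
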