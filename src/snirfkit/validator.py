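"""Rule-based SNIRF compliance checking with machine-readable reports.

``validate`` accepts either a file path or an in-memory :class:`SnirfFile`
and runs the full rule battery:

* minimum content — at least one nirs element, at least one data block,
  a probe with geometry for both sources and detectors;
* required metadata tags (subject identifier, acquisition date and time,
  length/time/frequency units);
* measurement-list length equal to the data-matrix column count;
* every sourceIndex / detectorIndex / wavelengthIndex within probe bounds;
* time-axis length and strict monotonicity;
* indexed-group contiguity starting at 1, index spelling (no zero-padding)
  and no bare/indexed name collisions (file input only — an in-memory model
  cannot express these);
* a parseable semantic ``formatVersion``;
* data-type registry membership (unknown codes are WARNING, since the format
  reserves codes for frequency-domain / time-domain / DCS channels without
  this tool enumerating them).

Findings carry a stable code, a severity, the absolute HDF5 path, a
human-readable message and a section anchor into the published format
specification. A report is *valid* iff it contains no FATAL or ERROR
finding; WARNINGs never flip validity. Finding order is deterministic:
sorted by location, then code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

from .exceptions import FormatError
from .model import (KNOWN_DATA_TYPES, DATA_TYPE_PROCESSED, DataBlock,
                    NirsElement, Probe, SnirfFile, expand_time)

__all__ = ["Severity", "Finding", "ValidationReport", "validate",
           "report_to_json", "report_from_json", "FINDING_CODES"]


class Severity(str, Enum):
    FATAL = "FATAL"
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


#: Closed registry of finding codes with their section anchors in the
#: published SNIRF format specification (also listed in docs/methods.md).
FINDING_CODES: dict[str, str] = {
    "UNREADABLE": "hdf5-container",
    "REQUIRED_MISSING": "required-data",
    "METADATA_MISSING": "metadata-tags",
    "INDEX_OUT_OF_RANGE": "measurement-list",
    "LIST_LENGTH_MISMATCH": "measurement-list",
    "TIME_LENGTH_MISMATCH": "time-axis",
    "TIME_NOT_INCREASING": "time-axis",
    "NONCONTIGUOUS_INDEX": "indexed-groups",
    "BAD_INDEX_NAME": "indexed-groups",
    "NAME_COLLISION": "indexed-groups",
    "VERSION_UNPARSEABLE": "format-version",
    "UNKNOWN_DATA_TYPE": "measurement-list",
    "DATA_TYPE_LABEL_MISSING": "measurement-list",
    "DIMENSION_MISMATCH": "probe",
    "NONPOSITIVE_WAVELENGTH": "probe",
    "EMPTY_DATA": "required-data",
}


@dataclass(frozen=True)
class Finding:
    """One severity-graded compliance observation at a specific HDF5 path."""

    code: str
    severity: Severity
    location: str
    message: str
    spec_ref: str

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity.value,
            "location": self.location,
            "message": self.message,
            "spec_ref": self.spec_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Finding":
        return cls(code=d["code"], severity=Severity(d["severity"]),
                   location=d["location"], message=d["message"],
                   spec_ref=d["spec_ref"])


@dataclass(frozen=True)
class ValidationReport:
    """Ordered findings plus the derived validity flag."""

    findings: tuple[Finding, ...]

    @property
    def valid(self) -> bool:
        return not any(f.severity in (Severity.FATAL, Severity.ERROR)
                       for f in self.findings)

    def by_code(self, code: str) -> list[Finding]:
        return [f for f in self.findings if f.code == code]

    def errors(self) -> list[Finding]:
        return [f for f in self.findings
                if f.severity in (Severity.FATAL, Severity.ERROR)]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == Severity.WARNING]


class _Collector:
    def __init__(self):
        self.findings: list[Finding] = []

    def add(self, code: str, severity: Severity, location: str,
            message: str) -> None:
        self.findings.append(Finding(code=code, severity=severity,
                                     location=location, message=message,
                                     spec_ref=FINDING_CODES[code]))

    def error(self, code: str, location: str, message: str) -> None:
        self.add(code, Severity.ERROR, location, message)

    def warning(self, code: str, location: str, message: str) -> None:
        self.add(code, Severity.WARNING, location, message)

    def report(self) -> ValidationReport:
        ordered = sorted(self.findings, key=lambda f: (f.location, f.code))
        return ValidationReport(findings=tuple(ordered))


def _parse_semver(version: str) -> bool:
    parts = version.strip().split(".")
    if len(parts) not in (2, 3):
        return False
    return all(p.isdigit() and p != "" for p in parts)


def _check_version(version: str, col: _Collector) -> None:
    if not version:
        return  # absence already reported as REQUIRED_MISSING by the reader
    if not _parse_semver(version):
        col.error("VERSION_UNPARSEABLE", "/formatVersion",
                  f"formatVersion '{version}' is not a MAJOR.MINOR[.PATCH] "
                  f"semantic version")


def _check_probe(probe: Probe, loc: str, col: _Collector) -> None:
    wl = np.asarray(probe.wavelengths, dtype=np.float64)
    if wl.size == 0:
        col.error("REQUIRED_MISSING", f"{loc}/wavelengths",
                  "probe must list at least one nominal wavelength")
    elif np.any(wl <= 0):
        col.error("NONPOSITIVE_WAVELENGTH", f"{loc}/wavelengths",
                  "nominal wavelengths must be strictly positive")

    if probe.source_pos_2d is None and probe.source_pos_3d is None:
        col.error("REQUIRED_MISSING", f"{loc}/sourcePos3D",
                  "probe carries neither sourcePos2D nor sourcePos3D")
    if probe.detector_pos_2d is None and probe.detector_pos_3d is None:
        col.error("REQUIRED_MISSING", f"{loc}/detectorPos3D",
                  "probe carries neither detectorPos2D nor detectorPos3D")

    for name, arr, width in (("sourcePos2D", probe.source_pos_2d, 2),
                             ("sourcePos3D", probe.source_pos_3d, 3),
                             ("detectorPos2D", probe.detector_pos_2d, 2),
                             ("detectorPos3D", probe.detector_pos_3d, 3)):
        if arr is None:
            continue
        a = np.asarray(arr)
        if a.ndim != 2 or a.shape[1] != width:
            col.error("DIMENSION_MISMATCH", f"{loc}/{name}",
                      f"{name} must be N x {width}, got shape {a.shape}")
    for kind, p2, p3 in (("source", probe.source_pos_2d, probe.source_pos_3d),
                         ("detector", probe.detector_pos_2d,
                          probe.detector_pos_3d)):
        if p2 is not None and p3 is not None:
            n2, n3 = np.asarray(p2).shape[0], np.asarray(p3).shape[0]
            if n2 != n3:
                col.error("DIMENSION_MISMATCH", f"{loc}/{kind}Pos3D",
                          f"2-D and 3-D {kind} arrays disagree on the "
                          f"number of optodes ({n2} vs {n3})")


def _check_time(time, n_rows: int, loc: str, col: _Collector) -> None:
    t = np.asarray(time, dtype=np.float64)
    if t.ndim != 1:
        col.error("TIME_LENGTH_MISMATCH", loc,
                  f"time axis must be 1-D, got shape {t.shape}")
        return
    if t.shape[0] == 2 and n_rows != 2:
        if float(t[1]) <= 0:
            col.error("TIME_NOT_INCREASING", loc,
                      f"implicit time increment {t[1]} is not positive")
        return
    if t.shape[0] != n_rows:
        col.error("TIME_LENGTH_MISMATCH", loc,
                  f"explicit time axis has {t.shape[0]} entries for "
                  f"{n_rows} samples")
        return
    if n_rows > 1 and not np.all(np.diff(t) > 0):
        col.error("TIME_NOT_INCREASING", loc,
                  "time values are not strictly increasing")


def _check_block(block: DataBlock, probe: Probe, loc: str,
                 col: _Collector) -> None:
    dts = np.asarray(block.data_time_series)
    if dts.ndim != 2:
        col.error("LIST_LENGTH_MISMATCH", loc,
                  f"dataTimeSeries must be 2-D, got shape {dts.shape}")
        return
    n_rows, n_cols = dts.shape
    n_ml = len(block.measurement_list)
    if n_cols != n_ml:
        col.error("LIST_LENGTH_MISMATCH", loc,
                  f"dataTimeSeries has {n_cols} columns but the measurement "
                  f"list has {n_ml} elements")
    if n_cols == 0 and n_ml == 0:
        col.error("EMPTY_DATA", loc,
                  "data block contains zero channels; a compliant file "
                  "needs at least one series of raw data")

    _check_time(block.time, n_rows, f"{loc}/time", col)

    n_wl = int(np.asarray(probe.wavelengths).size)
    n_src = probe.n_sources
    n_det = probe.n_detectors
    for k, ml in enumerate(block.measurement_list, start=1):
        ml_loc = f"{loc}/{ml.h5_name or f'measurementList{k}'}"
        for field, value, bound in (("sourceIndex", ml.source_index, n_src),
                                    ("detectorIndex", ml.detector_index,
                                     n_det),
                                    ("wavelengthIndex", ml.wavelength_index,
                                     n_wl)):
            if bound is None:
                continue  # missing probe arrays already reported
            if not 1 <= value <= bound:
                col.error("INDEX_OUT_OF_RANGE", f"{ml_loc}/{field}",
                          f"{field} = {value} is outside 1..{bound}")
        if ml.data_type == DATA_TYPE_PROCESSED and not ml.data_type_label:
            col.error("DATA_TYPE_LABEL_MISSING", ml_loc,
                      f"dataType {DATA_TYPE_PROCESSED} (processed) requires "
                      f"a dataTypeLabel")
        elif ml.data_type not in KNOWN_DATA_TYPES:
            col.warning("UNKNOWN_DATA_TYPE", f"{ml_loc}/dataType",
                        f"dataType {ml.data_type} is not in the known "
                        f"registry; treated as an opaque modality code")


def _check_element(el: NirsElement, loc: str, col: _Collector,
                   from_file: bool) -> None:
    for tag in el.metadata.missing_required():
        col.error("METADATA_MISSING", f"{loc}/metaDataTags",
                  f"required metadata tag '{tag}' is missing or empty")

    # permissive reads report an absent probe themselves; a synthesized
    # placeholder probe must not trigger duplicate geometry findings
    probe_absent_on_read = (from_file and el.probe.n_sources is None
                            and el.probe.n_detectors is None
                            and np.asarray(el.probe.wavelengths).size == 0
                            and not el.probe.extra)
    if not probe_absent_on_read:
        _check_probe(el.probe, f"{loc}/probe", col)

    if not el.data:
        col.error("REQUIRED_MISSING", loc,
                  "nirs element contains no data blocks; at least one "
                  "series of raw data is required")
    for j, block in enumerate(el.data, start=1):
        block_loc = f"{loc}/{block.h5_name or f'data{j}'}"
        _check_block(block, el.probe, block_loc, col)

    for j, stim in enumerate(el.stim, start=1):
        stim_loc = f"{loc}/{stim.h5_name or f'stim{j}'}"
        data = np.asarray(stim.data, dtype=np.float64)
        if data.size and (data.ndim != 2 or data.shape[1] != 3):
            col.error("DIMENSION_MISMATCH", f"{stim_loc}/data",
                      f"stim data must be E x 3 [onset, duration, "
                      f"amplitude], got shape {data.shape}")
            continue
        if data.size:
            if np.any(np.diff(data[:, 0]) < 0):
                col.warning("TIME_NOT_INCREASING", f"{stim_loc}/data",
                            "stim onsets are not non-decreasing")
            if np.any(data[:, 1] < 0):
                col.warning("DIMENSION_MISMATCH", f"{stim_loc}/data",
                            "stim durations should be non-negative")

    for j, aux in enumerate(el.aux, start=1):
        aux_loc = f"{loc}/{aux.h5_name or f'aux{j}'}"
        _check_time(aux.time, aux.n_rows, f"{aux_loc}/time", col)


def _validate_model(model: SnirfFile, col: _Collector,
                    from_file: bool) -> None:
    _check_version(model.format_version, col)
    if not model.nirs and not from_file:
        col.error("REQUIRED_MISSING", "/", "file contains no nirs groups")
    names = ([el.h5_name for el in model.nirs]
             if from_file else None)
    for i, el in enumerate(model.nirs, start=1):
        if names and names[i - 1]:
            name = names[i - 1]
        else:
            name = "nirs" if len(model.nirs) == 1 else f"nirs{i}"
        _check_element(el, f"/{name}", col, from_file)


def validate(target: Union[str, "SnirfFile"]) -> ValidationReport:
    """Check a file path or in-memory model for format compliance.

    Never raises for damaged input: an unreadable container yields a single
    FATAL finding with ``valid=False``. The same file bytes always produce
    the same report.
    """
    col = _Collector()
    if isinstance(target, SnirfFile):
        _validate_model(target, col, from_file=False)
        return col.report()

    from .io import read_snirf_permissive

    try:
        model, issues = read_snirf_permissive(target)
    except FormatError as exc:
        col.add("UNREADABLE", Severity.FATAL, "/", str(exc))
        return col.report()
    for issue in issues:
        col.error(issue.code, issue.location, issue.message)
    _validate_model(model, col, from_file=True)
    return col.report()


# ---------------------------------------------------------------------------
# machine-readable reports
# ---------------------------------------------------------------------------

_SCHEMA_ID = "snirfkit-validation-report/1"


def report_to_json(report: ValidationReport) -> str:
    """Serialize a report to the stable JSON document described by
    ``snirfkit/schemas/validation_report.schema.json``. Serialization is
    deterministic; serialize -> parse -> serialize is byte-identical."""
    doc = {
        "schema": _SCHEMA_ID,
        "valid": report.valid,
        "findings": [f.to_dict() for f in report.findings],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def report_from_json(text: str) -> ValidationReport:
    """Parse a report document produced by :func:`report_to_json`."""
    doc = json.loads(text)
    if doc.get("schema") != _SCHEMA_ID:
        raise ValueError(f"unknown report schema: {doc.get('schema')!r}")
    return ValidationReport(
        findings=tuple(Finding.from_dict(d) for d in doc["findings"]))
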