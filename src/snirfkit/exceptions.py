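"""Exception hierarchy for snirfkit.

All library-specific errors derive from :class:`SnirfError` so callers can
catch one base class at an API boundary (the CLI maps them to exit codes).
"""


class SnirfError(Exception):
    """Base class for all snirfkit errors."""


class FormatError(SnirfError):
    """The target is not an HDF5 container at all."""


class StructuralError(SnirfError):
    """The container is HDF5 but violates the SNIRF hierarchy contract
    (e.g. missing /formatVersion, time axis of the wrong length)."""


class NamingError(SnirfError):
    """An indexed-group name is malformed (zero-padded index, bare name
    colliding with indexed siblings)."""


class SnirfIndexError(SnirfError, IndexError):
    """A 1-based block/channel index is outside its collection. Carries the
    offending HDF5-style path in the message."""


class CrossReferenceError(SnirfError):
    """A measurement-list index does not resolve into the probe arrays
    (dangling sourceIndex/detectorIndex/wavelengthIndex)."""


class ValidationError(SnirfError):
    """Raised by the writer when asked to serialize a non-compliant model
    without ``force``; carries the validation report."""

    def __init__(self, report):
        self.report = report
        lines = [f"{f.severity.value} {f.code} at {f.location}: {f.message}"
                 for f in report.findings]
        super().__init__("model fails validation:\n" + "\n".join(lines))
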