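# Methods

## The format in brief

SNIRF (Shared NIRS Format) stores functional near-infrared spectroscopy
recordings in an HDF5 container. The root holds a semantic-version string
(`/formatVersion`) and one or more `nirs` recording units. Each unit holds:

- **metaDataTags** — string key/value descriptors. Six are mandatory:
  `SubjectID`, `MeasurementDate` (ISO-8601 date), `MeasurementTime`
  (ISO-8601 time), `LengthUnit`, `TimeUnit`, `FrequencyUnit`. Anything else
  the user adds is preserved byte-exactly on round trip.
- **probe** — acquisition geometry: nominal `wavelengths` (nm, strictly
  positive) and optode coordinates. Sources and detectors may each be given
  in 2-D and/or 3-D (`sourcePos2D`/`sourcePos3D`, `detectorPos2D`/
  `detectorPos3D`, in `LengthUnit`); when both layouts exist their row
  counts must agree.
- **data1..dataN** — time × channel matrices (`dataTimeSeries`, rows =
  samples, columns = channels) with a time axis and a *measurement list*.
- **stim**, **aux** — optional stimulus descriptors and auxiliary signals
  (e.g. accelerometers) with their own clocks.

### Measurement-list resolution

`measurementList{k}` describes column *k* of its block's matrix through
three 1-based indices — `sourceIndex`, `detectorIndex`, `wavelengthIndex` —
into the probe arrays, plus a `dataType` code (1 = raw continuous-wave
amplitude; 99999 = processed, which requires a `dataTypeLabel`; other codes
are reserved for frequency-domain/time-domain/DCS channels and are accepted
as opaque). `resolve_channel` follows these indices and returns the source
and detector positions and the nominal wavelength; when a probe carries
both 2-D and 3-D layouts the 3-D coordinates are returned, since the 3-D
form is the richer description. All indices stay 1-based end to end;
conversion to Python indexing happens only at array access.

### Indexed groups

Repeatable groups share a base name with decimal suffixes starting at 1
and no zero-padding (`stim1`, `stim2`, `stim3`). A bare base name is legal
only as the sole member of its collection. The writer emits a bare `nirs`
for single-recording files and always-indexed `data1`, `measurementList1`,
`stim1`, `aux1`; the reader accepts both the bare and the `...1` singleton
dialects, since both occur in vendor exports.

### Time axes

Signals in one file may have different sampling rates and onsets, so every
block and aux signal carries its own axis in one of two encodings: an
explicit array of sample times, or a length-2 `[start, increment]` pair
that expands to `start + k*increment`. A length-2 array attached to a
block with exactly two rows is ambiguous between the encodings; this
package resolves it as *explicit*, which is the only reading under which
the stored values are themselves the sample times. `expand_time` is
idempotent on its own output.

## Validator design

`validate` accepts a path or an in-memory model and returns an ordered
report of findings, each with a stable code, a severity, the absolute HDF5
path, a message, and a section anchor into the published format
specification. Severities: **FATAL** (container unreadable), **ERROR**
(specification violation — file is non-compliant), **WARNING**
(interoperability risk, e.g. an unknown `dataType` code), **INFO**. A file
is valid iff no FATAL/ERROR findings exist; warnings never flip validity.
Finding order is deterministic (location, then code), and the same bytes
always produce the same report.

Reading for validation is *permissive*: structural and naming violations
are collected, not raised, so a damaged file still yields a complete
report rather than an exception. The full code registry is the
`FINDING_CODES` mapping in `snirfkit.validator` and the shipped JSON
schema (`snirfkit/schemas/validation_report.schema.json`), which is the
contract for `report_to_json` output. The CLI exit contract is 0 = valid,
1 = ERROR-level findings, 2 = unreadable.

Decisions taken where the format leaves room:

- Unknown `dataType` codes are WARNING, not ERROR: the format reserves
  modality-specific codes this tool does not enumerate.
- Indexed-group contiguity violations (e.g. `stim1`, `stim3` with no
  `stim2`) are ERROR: the 1..N convention is normative.
- A zero-channel block (0-column matrix with empty measurement list) is
  ERROR (`EMPTY_DATA`): a compliant file needs at least one series of raw
  data.
- Probe dimension mismatches (e.g. `sourcePos3D` not S×3, or 2-D/3-D row
  counts disagreeing) are ERROR; *absence* of the 2-D layout when 3-D
  exists is not a finding.
- Stimulus columns are interpreted as `[onset, duration, amplitude]` in
  `TimeUnit`. This is community practice rather than a normative rule, so
  non-monotone onsets and negative durations are WARNING; a wrong column
  count is ERROR. Detector-index resolution mirrors source-index
  resolution.
- The validator never mutates or repairs files.

## Serialization choices

Floating-point data are stored as 64-bit, index fields as 32-bit signed
integers, strings as variable-length UTF-8. The reader additionally
accepts fixed-length byte strings, any numeric width, chunked/compressed
datasets, and flat single-channel `dataTimeSeries` vectors (reshaped to
T×1). Unrecognized datasets inside recognized groups are retained in a
per-object `extra` preservation area and written back unchanged — the
format's self-describing intent means nothing is silently dropped.
`read(write(m)) == m` holds exactly for stored values. Datasets are
created with `track_times=False`, so identical models produce
byte-identical files; no compression is applied on write.

## Synthetic fixtures

The generator emulates the *structure* of a multi-block continuous-wave
recording at desk scale (caps: 32 sources/detectors, 8 blocks, 10 min):

- optodes on a planar grid at 30 mm spacing (the typical adult
  source-detector separation), detectors offset half a cell;
- channels enumerated source-major over all (source, detector, wavelength)
  triples, so expected measurement lists are reproducible; the default
  distance cap is infinite (all pairs);
- per-channel signals = 1.0 baseline + 0.05 sinusoid at 1.1 Hz
  (cardiac band) + 0.01 sinusoid at 0.25 Hz (respiration) + 0.02 boxcar
  during stimulus events + Gaussian noise (σ = 0.005), defaults chosen as
  plausible normalized CW intensities;
- blocks get independent rates and sub-second random onsets, alternating
  explicit and implicit time encodings; aux signals run at their own rates;
- stimulus onsets drawn uniformly over the first 80% of the recording,
  then sorted; default wavelengths 760/850 nm, the common CW pair.

Everything is a pure function of the spec (including its seed); identical
specs yield byte-identical files. The physiology is deliberately
schematic — no hemodynamic response function, optical densities,
wavelength-dependent amplitudes, motion artifacts or vendor quirks beyond
the string-encoding dialects noted above. Passing tests therefore
demonstrate correct *storage, resolution and rule checking*, not fidelity
to real cortical signals.

`corrupt` writes a valid model and seeds exactly one named defect by
direct HDF5 surgery (14 defects, registry `DEFECTS`), returning the
location and code the validator must report. The test suite checks the
full one-defect/one-detection matrix and that uncorrupted twins carry zero
ERROR findings. A seeded defect may entail secondary findings (renaming
`stim1` to `stim01` also leaves the collection non-contiguous); the matrix
requires the mapped code at the seeded location and tolerates such
side-effects.

## Problem sizes

The test suite runs the round-trip identity over 200 randomized small
specs (≤3 sources/detectors, ≤2 blocks, ≤1.5 s), the oracle-equivalence
sweep up to 16×16×3 = 768 channels, and the full defect matrix; the whole
suite completes in well under a minute on one CPU. These sizes exercise
every code path; the format itself has no behavior that emerges only at
scale.

## Known limitations

- Frequency-domain, time-domain and DCS channels are carried as opaque
  `dataType` codes; their modality-specific fields are not modeled or
  validated.
- No hemodynamic analysis (optical density, Beer–Lambert conversion),
  motion correction or image reconstruction.
- No auto-transposition of `dataTimeSeries`: a transposed matrix surfaces
  as a measurement-list length mismatch rather than being silently fixed.
- No BIDS-layout validation, vendor-native conversion, streaming writes or
  HDF5 external links.
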