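# snirfkit

Read, write, validate and synthesize **SNIRF** (Shared NIRS Format) files —
the HDF5-based container for functional near-infrared spectroscopy (fNIRS)
recordings.

fNIRS instruments measure light attenuation between scalp-mounted optodes;
a *channel* is the time series for one source–detector pair at one nominal
wavelength. SNIRF stores the channel matrix (`dataTimeSeries`, time ×
channel), the probe geometry (`sourcePos3D`, `detectorPos3D`,
`wavelengths`), and a *measurement list* that links column *k* of the
matrix to the probe through 1-based indices: `measurementList{k}` carries
`sourceIndex`, `detectorIndex` and `wavelengthIndex`, so

```
channel k  →  (sourcePos[sourceIndex], detectorPos[detectorIndex],
               wavelengths[wavelengthIndex])
```

Repeatable groups use the *indexed group* convention (`stim1`, `stim2`,
`stim3`, … starting at 1, no zero-padding), files carry self-describing
metadata tags, and every data block and auxiliary signal may have its own
sampling rate and onset. This package is aimed at tool developers and
researchers who need a dependable SNIRF backend: a typed in-memory model,
lossless HDF5 round-tripping tolerant of vendor dialects, a rule-based
compliance validator with machine-readable reports, and a synthetic
fixture generator (with a single-defect corruptor) so everything is
testable without downloading data.

## Worked example

The bundled worked-example fixture demonstrates measurement-list
resolution: its `measurementList2` points at the probe's second source and
second wavelength.

```python
from snirfkit import make_fig2_example, write_snirf, read_snirf, resolve_channel

write_snirf(make_fig2_example(), "fig2.snirf")
element = read_snirf("fig2.snirf").nirs[0]
print(resolve_channel(element, block_index=1, channel_index=2))
```

prints

```
ChannelDescription(source_position=(42.0, -125.0, 42.0), detector_position=(0.0, -110.0, 55.0), wavelength=830.0, data_type=1, column_index=2)
```

i.e. the signal in column 2 of the data matrix was produced at the optode
at [42.0, −125.0, 42.0] (in the file's `LengthUnit`, mm) by a source with
a nominal wavelength of 830 nm — the channel's identity fully recovered
from the indices alone.

The same file through the CLI:

```
$ snirf create-example fig2 fig2.snirf
wrote fig2 example to fig2.snirf
$ snirf info fig2.snirf
formatVersion: 1.0
nirs 1:
  subject: sub-01
  wavelengths (nm): 690, 830
  data blocks: 1
    block 1: 4 channels, 10 samples, 10 Hz
  stim: tapping
$ snirf validate fig2.snirf
fig2.snirf: valid (0 warning(s))
```

`snirf validate --json report.json` writes the findings in the stable JSON
schema shipped at `src/snirfkit/schemas/validation_report.schema.json`;
exit status is 0 (valid), 1 (ERROR findings) or 2 (unreadable). `snirf
export` dumps a block as a tab-delimited table with `S{s}_D{d}_{wl}nm`
column headers (a non-normative convention of this tool), and `snirf
selftest` runs the generator/corruptor matrix against the validator.

## Validation

`validate(path_or_model)` runs the full rule battery — minimum content
(≥1 `nirs`, ≥1 data block, a probe), the six required metadata tags,
measurement-list length vs. column count, probe index bounds, time-axis
length/monotonicity, indexed-group contiguity and spelling, semantic
`formatVersion`, and data-type registry membership — and returns
severity-graded findings with stable codes and HDF5 paths. Damaged files
are read permissively so the report is always complete; see
`docs/methods.md` for the code registry and severity rationale.

## Synthetic fixtures

`generate(GenSpec(...))` builds seed-deterministic, structurally realistic
continuous-wave recordings (grid probe, sinusoidal physiology + noise +
stimulus-locked boxcars, per-block clocks); `corrupt(model, defect, path)`
seeds exactly one of 14 named defects and returns where the validator must
flag it. `build_corpus(dir)` emits the whole corpus (`valid/` and
`corrupted/<defect>/`).

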