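{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "snirfkit-validation-report/1",
  "title": "snirfkit validation report",
  "description": "Machine-readable SNIRF compliance report: an ordered list of severity-graded findings, each anchored to an absolute HDF5 path and a section of the published SNIRF format specification. 'valid' is true iff no finding has severity FATAL or ERROR.",
  "type": "object",
  "required": ["schema", "valid", "findings"],
  "properties": {
    "schema": {
      "const": "snirfkit-validation-report/1"
    },
    "valid": {
      "type": "boolean"
    },
    "findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "severity", "location", "message", "spec_ref"],
        "properties": {
          "code": {
            "type": "string",
            "enum": [
              "UNREADABLE",
              "REQUIRED_MISSING",
              "METADATA_MISSING",
              "INDEX_OUT_OF_RANGE",
              "LIST_LENGTH_MISMATCH",
              "TIME_LENGTH_MISMATCH",
              "TIME_NOT_INCREASING",
              "NONCONTIGUOUS_INDEX",
              "BAD_INDEX_NAME",
              "NAME_COLLISION",
              "VERSION_UNPARSEABLE",
              "UNKNOWN_DATA_TYPE",
              "DATA_TYPE_LABEL_MISSING",
              "DIMENSION_MISMATCH",
              "NONPOSITIVE_WAVELENGTH",
              "EMPTY_DATA"
            ]
          },
          "severity": {
            "type": "string",
            "enum": ["FATAL", "ERROR", "WARNING", "INFO"]
          },
          "location": {
            "type": "string",
            "description": "Absolute HDF5 path of the offending object"
          },
          "message": {
            "type": "string"
          },
          "spec_ref": {
            "type": "string",
            "description": "Section anchor in the published SNIRF format specification"
          }
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
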