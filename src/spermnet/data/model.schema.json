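{
  "$comment": "Human-readable description of the spermnet model-file format. Validation is performed structurally by spermnet.io.read_model, which checks everything described here and reports the offending node and row.",
  "type": "object",
  "required": ["name", "nodes", "tables"],
  "properties": {
    "name": {"type": "string"},
    "metadata": {"type": "object"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "arity", "levels", "regulators"],
        "properties": {
          "name": {"type": "string", "description": "unique node identifier"},
          "arity": {"type": "integer", "minimum": 2},
          "levels": {"type": "array", "items": {"type": "string"},
                     "description": "one label per level (length == arity)"},
          "regulators": {"type": "array", "items": {"type": "string"},
                         "description": "ordered list of node names; no duplicates"}
        }
      }
    },
    "tables": {
      "type": "object",
      "description": "per node name: complete truth table; each row is the input tuple in regulator order followed by the output level; exactly prod(regulator arities) rows, no duplicates, outputs < arity"
    }
  }
}
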