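{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "kmervar targeted-assembly neighborhood graph",
  "description": "Compacted-unitig graph around a starter sequence. Node sequences on an edge overlap by exactly k-1 characters consistent with orientation; exactly one node has is_starter true. 'cov' holds one mean k-mer-window count per input read set, in input order.",
  "type": "object",
  "required": ["k", "starter", "nodes", "edges"],
  "properties": {
    "k": {"type": "integer", "minimum": 3, "maximum": 31},
    "starter": {"type": "integer", "description": "id of the starter node"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "seq", "cov", "is_starter"],
        "properties": {
          "id": {"type": "integer", "minimum": 0},
          "seq": {"type": "string", "pattern": "^[ACGTN]+$"},
          "cov": {"type": "array", "items": {"type": "number", "minimum": 0}},
          "is_starter": {"type": "boolean"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["from", "to"],
        "properties": {
          "from": {"type": "integer"},
          "to": {"type": "integer"}
        }
      }
    }
  }
}
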