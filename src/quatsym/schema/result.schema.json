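{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "quatsym symmetry result",
  "type": "object",
  "required": [
    "entry_id", "assembly_id", "mode", "stoichiometry", "group",
    "order", "max_rmsd", "axes", "operations", "helical", "excluded_subunits"
  ],
  "properties": {
    "entry_id": {"type": "string"},
    "assembly_id": {"type": "string"},
    "mode": {"enum": ["symmetric", "pseudo-symmetric", "asymmetric"]},
    "stoichiometry": {
      "type": "object",
      "required": ["composition", "counts", "category"],
      "properties": {
        "composition": {"type": "string"},
        "counts": {"type": "object", "additionalProperties": {"type": "integer"}},
        "category": {"enum": ["monomer", "homomer", "heteromer", "none"]}
      }
    },
    "group": {"type": "string", "pattern": "^(C[0-9]+|D[0-9]+|T|O|I|H)$"},
    "order": {"type": "integer", "minimum": 0},
    "max_rmsd": {"type": "number", "minimum": 0},
    "axes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["vector", "fold", "angle_deg"],
        "properties": {
          "vector": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
          "fold": {"type": ["integer", "null"]},
          "angle_deg": {"type": "number"}
        }
      }
    },
    "operations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["rmsd", "permutation"],
        "properties": {
          "rmsd": {"type": "number", "minimum": 0},
          "permutation": {"type": "object", "additionalProperties": {"type": "string"}}
        }
      }
    },
    "helical": {
      "type": ["object", "null"],
      "required": ["axis", "rise", "twist", "n_subunits"],
      "properties": {
        "axis": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
        "rise": {"type": "number"},
        "twist": {"type": "number"},
        "n_subunits": {"type": "integer", "minimum": 3}
      }
    },
    "excluded_subunits": {"type": "array", "items": {"type": "string"}}
  }
}
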