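{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Criteria definition",
  "description": "Declarative definition of a rule-based classification criteria set. Predicates are boolean expressions (and/or/not, parentheses) over the declared feature vocabulary. Validation is enforced at load time by the package's pydantic models; this document describes the accepted shape.",
  "type": "object",
  "required": ["name", "rule_kind", "threshold", "items"],
  "additionalProperties": false,
  "properties": {
    "name": {"type": "string"},
    "rule_kind": {
      "enum": ["weighted_sum_threshold", "count_threshold", "domain_weighted_threshold"]
    },
    "threshold": {"type": "number"},
    "threshold_is_strict": {"type": "boolean", "default": false},
    "entry": {"type": "string", "description": "entry predicate; classification impossible when unsatisfied"},
    "min_clinical": {"type": "integer", "minimum": 0, "default": 0},
    "min_immunologic": {"type": "integer", "minimum": 0, "default": 0},
    "standalone": {
      "type": "array",
      "items": {"type": "string"},
      "description": "predicates that each classify on their own"
    },
    "items": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["item_id", "predicate"],
        "additionalProperties": false,
        "properties": {
          "item_id": {"type": "string"},
          "predicate": {"type": "string"},
          "weight": {"type": "number", "default": 1.0},
          "domain": {"type": "string"},
          "category": {"enum": ["clinical", "immunologic", "none"], "default": "none"}
        }
      }
    },
    "probability_transform": {
      "type": "object",
      "required": ["intercept", "coefficients"],
      "properties": {
        "intercept": {"type": "number"},
        "coefficients": {"type": "object", "additionalProperties": {"type": "number"}}
      }
    },
    "category_cutpoints": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 3,
      "maxItems": 3,
      "description": "ascending percentage bounds between unlikely/possible/likely/definite"
    }
  }
}
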