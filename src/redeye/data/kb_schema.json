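{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "redeye knowledge base",
  "type": "object",
  "required": ["diagnoses", "questions"],
  "properties": {
    "settings": {
      "type": "object",
      "properties": {
        "theta": {"type": "number", "minimum": 1},
        "posterior_stop": {"type": "number", "minimum": 0, "maximum": 1},
        "voi_mode": {"enum": ["max", "expected"]}
      },
      "additionalProperties": false
    },
    "diagnoses": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "urgent": {"type": "boolean"},
          "prior": {"type": "number", "minimum": 0}
        },
        "additionalProperties": false
      }
    },
    "questions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "text", "answer_model"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "text": {"type": "string", "minLength": 1},
          "opening": {"type": "boolean"},
          "answer_model": {
            "type": "object",
            "description": "diagnosis id (or 'default') -> P(YES | diagnosis)",
            "additionalProperties": {
              "type": "number", "minimum": 0, "maximum": 1
            }
          },
          "prerequisites": {"$ref": "#/$defs/answerPairList"},
          "redundancy_triggers": {"$ref": "#/$defs/answerPairList"}
        },
        "additionalProperties": false
      }
    },
    "advice": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "message"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "message": {"type": "string", "minLength": 1},
          "when": {
            "type": "object",
            "properties": {
              "answers": {"$ref": "#/$defs/answerPairList"},
              "min_posterior": {
                "type": "object",
                "minProperties": 1,
                "maxProperties": 1,
                "additionalProperties": {
                  "type": "number", "minimum": 0, "maximum": 1
                }
              }
            },
            "additionalProperties": false
          }
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false,
  "$defs": {
    "answerPairList": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [
          {"type": "string"},
          {"enum": ["yes", "no", "unknown"]}
        ],
        "minItems": 2,
        "maxItems": 2
      }
    }
  }
}
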