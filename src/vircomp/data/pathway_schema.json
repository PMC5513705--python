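{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "vircomp pathway database",
 "description": "Single JSON document holding a list of pathways: directed compound-reaction graphs with protein complexes and two-component regulatory rules. Defaults: reversible=false, is_seed=false, is_target=false.",
 "type": "object",
 "required": ["pathways"],
 "properties": {
  "pathways": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "compounds", "reactions"],
    "properties": {
     "id": {"type": "string"},
     "name": {"type": "string"},
     "compounds": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["id"],
       "properties": {
        "id": {"type": "string"},
        "name": {"type": "string"},
        "is_seed": {"type": "boolean", "default": false},
        "is_target": {"type": "boolean", "default": false}
       }
      }
     },
     "reactions": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["id", "substrates", "products"],
       "properties": {
        "id": {"type": "string"},
        "ec": {"type": ["string", "null"], "pattern": "^\\d+\\.\\d+\\.\\d+\\.(\\d+|-)$"},
        "symbol": {"type": ["string", "null"]},
        "substrates": {"type": "array", "items": {"type": "string"}, "minItems": 1},
        "products": {"type": "array", "items": {"type": "string"}, "minItems": 1},
        "reversible": {"type": "boolean", "default": false}
       }
      }
     },
     "complexes": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["id", "subunits"],
       "properties": {
        "id": {"type": "string"},
        "subunits": {"type": "array", "items": {"type": "string"}, "minItems": 2},
        "function": {"type": "string"}
       }
      }
     },
     "rules": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["id", "signal", "effects"],
       "properties": {
        "id": {"type": "string"},
        "signal": {"type": "string"},
        "sensor": {"type": ["string", "null"]},
        "regulator": {"type": ["string", "null"]},
        "effects": {
         "type": "array",
         "items": {
          "type": "object",
          "required": ["target", "mode"],
          "properties": {
           "target": {"type": "string"},
           "mode": {"enum": ["activate", "inhibit"]}
          }
         }
        }
       }
      }
     }
    }
   }
  }
 }
}
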