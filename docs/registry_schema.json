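{
  "$comment": "Informal schema of the mobykit registry store (schema_version 1). Validation is performed structurally by mobykit.store; this document describes the shape for integrators.",
  "type": "object",
  "required": ["schema_version", "datatypes", "categories", "namespaces", "tools", "locations"],
  "properties": {
    "schema_version": {"const": 1},
    "datatypes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "description": {"type": "string"},
          "is_parent": {"type": ["string", "null"]},
          "attributes": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [
                {"type": "string"},
                {"enum": ["String", "Integer", "Float", "Boolean"]}
              ]
            }
          },
          "has_parts": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [{"type": "string"}, {"type": "string"}]
            }
          },
          "hasa_parts": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [{"type": "string"}, {"type": "string"}]
            }
          }
        }
      }
    },
    "categories": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "description": {"type": "string"},
          "parent": {"type": ["string", "null"]}
        }
      }
    },
    "namespaces": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "description": {"type": "string"},
          "source_note": {"type": "string"}
        }
      }
    },
    "tools": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "description": {"type": "string"},
          "category_refs": {"type": "array", "items": {"type": "string"}},
          "operations": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "name"],
              "properties": {
                "id": {"type": "string"},
                "name": {"type": "string"},
                "virtual": {"type": "boolean"},
                "parameters": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["id", "name", "kind", "datatype_ref"],
                    "properties": {
                      "id": {"type": "string"},
                      "name": {"type": "string"},
                      "kind": {"enum": ["input", "output", "secondary"]},
                      "datatype_ref": {"type": "string"},
                      "namespace_ref": {"type": ["string", "null"]},
                      "cardinality": {"enum": ["one", "many"]}
                    }
                  }
                }
              }
            }
          }
        }
      }
    },
    "locations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "tool_ref", "protocol", "endpoint"],
        "properties": {
          "id": {"type": "string"},
          "tool_ref": {"type": "string"},
          "protocol": {"type": "string"},
          "endpoint": {"type": "string"},
          "host_info": {"type": "object", "additionalProperties": {"type": "string"}}
        }
      }
    },
    "engine_config": {
      "type": "object",
      "properties": {
        "disabled_loaders": {"type": "array", "items": {"type": "string"}}
      }
    },
    "statistics": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "count": {"type": "integer"},
          "success": {"type": "integer"},
          "latency": {"type": "number"}
        }
      }
    }
  }
}
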