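{
  "$id": "bioecon/report_schema.json",
  "title": "bioecon pipeline report",
  "type": "object",
  "required": ["schema_version", "provenance", "impacts", "projections", "cba", "rounding"],
  "properties": {
    "schema_version": {"type": "string"},
    "provenance": {
      "type": "object",
      "required": ["package", "version", "seed", "config_hash", "table_source", "config"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "config_hash": {"type": "string"},
        "table_source": {"type": "string"},
        "config": {"type": "object"}
      }
    },
    "impacts": {
      "type": "object",
      "required": ["base", "adjusted", "incremental"],
      "properties": {
        "base": {"$ref": "#/$defs/impact"},
        "adjusted": {"$ref": "#/$defs/impact"},
        "incremental": {"type": "array", "items": {"type": "number"}}
      }
    },
    "projections": {
      "type": "object",
      "required": ["initial_annual_benefit", "annual_growth", "calibrated", "anchors", "totals"],
      "properties": {
        "initial_annual_benefit": {"type": "number"},
        "annual_growth": {"type": "number"},
        "calibrated": {"type": "boolean"},
        "anchors": {
          "type": ["array", "null"],
          "items": {"type": "array", "items": {"type": "number"}}
        },
        "totals": {"type": "object"}
      }
    },
    "cba": {
      "type": "object",
      "required": [
        "pv_benefits", "pv_costs", "npv", "bcr",
        "total_benefits", "total_costs",
        "discount_rate", "horizon_years", "cost_spread_years"
      ],
      "properties": {
        "pv_benefits": {"type": "number"},
        "pv_costs": {"type": "number"},
        "npv": {"type": "number"},
        "bcr": {"type": ["number", "null"]},
        "total_benefits": {"type": "number"},
        "total_costs": {"type": "number"},
        "discount_rate": {"type": "number"},
        "horizon_years": {"type": "integer"},
        "cost_spread_years": {"type": "integer"}
      }
    },
    "rounding": {
      "type": "object",
      "required": ["currency_decimals", "share_decimals"],
      "properties": {
        "currency_decimals": {"type": "integer"},
        "share_decimals": {"type": "integer"},
        "note": {"type": "string"}
      }
    }
  },
  "$defs": {
    "impact": {
      "type": "object",
      "required": ["labels", "direct", "indirect", "induced", "total", "shares", "closure_type"],
      "properties": {
        "labels": {"type": "array", "items": {"type": "string"}},
        "direct": {"type": "array", "items": {"type": "number"}},
        "indirect": {"type": "array", "items": {"type": "number"}},
        "induced": {"type": "array", "items": {"type": "number"}},
        "total": {"type": "array", "items": {"type": "number"}},
        "shares": {"type": ["array", "null"], "items": {"type": "number"}},
        "closure_type": {"type": "string", "enum": ["type_I", "type_II"]}
      }
    }
  }
}
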