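{
 "$defs": {
  "AlertDisplay": {
   "description": "What the prescriber sees for one alert.",
   "properties": {
    "alert_id": {
     "title": "Alert Id",
     "type": "string"
    },
    "use_case": {
     "title": "Use Case",
     "type": "string"
    },
    "text": {
     "title": "Text",
     "type": "string"
    },
    "description": {
     "title": "Description",
     "type": "string"
    },
    "recommendation": {
     "title": "Recommendation",
     "type": "string"
    },
    "color": {
     "title": "Color",
     "type": "string"
    },
    "level": {
     "title": "Level",
     "type": "string"
    },
    "link": {
     "default": "",
     "title": "Link",
     "type": "string"
    }
   },
   "required": [
    "alert_id",
    "use_case",
    "text",
    "description",
    "recommendation",
    "color",
    "level"
   ],
   "title": "AlertDisplay",
   "type": "object"
  },
  "ScoreBlock": {
   "properties": {
    "mrci_section_a": {
     "default": 0.0,
     "title": "Mrci Section A",
     "type": "number"
    },
    "mrci_section_b": {
     "default": 0.0,
     "title": "Mrci Section B",
     "type": "number"
    },
    "mrci_section_c": {
     "default": 0.0,
     "title": "Mrci Section C",
     "type": "number"
    },
    "mrci_total": {
     "default": 0.0,
     "title": "Mrci Total",
     "type": "number"
    },
    "dbi_total": {
     "default": 0.0,
     "title": "Dbi Total",
     "type": "number"
    },
    "dbi_terms": {
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "title": "Dbi Terms",
     "type": "array"
    },
    "trigger_hits": {
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "title": "Trigger Hits",
     "type": "array"
    }
   },
   "title": "ScoreBlock",
   "type": "object"
  },
  "TraceRecord": {
   "properties": {
    "at": {
     "format": "date-time",
     "title": "At",
     "type": "string"
    },
    "patient_id": {
     "default": "",
     "title": "Patient Id",
     "type": "string"
    },
    "rule": {
     "default": "",
     "title": "Rule",
     "type": "string"
    },
    "outcome": {
     "default": "",
     "title": "Outcome",
     "type": "string"
    },
    "detail": {
     "additionalProperties": true,
     "title": "Detail",
     "type": "object"
    }
   },
   "title": "TraceRecord",
   "type": "object"
  }
 },
 "description": "Top-level JSON response; ``status`` is \"ok\" for any completed\nevaluation (even a partial one with trace annotations) and\n\"invalid_request\" when the document never parsed.",
 "properties": {
  "status": {
   "enum": [
    "ok",
    "invalid_request"
   ],
   "title": "Status",
   "type": "string"
  },
  "patient_id": {
   "default": "",
   "title": "Patient Id",
   "type": "string"
  },
  "eligible": {
   "default": false,
   "title": "Eligible",
   "type": "boolean"
  },
  "scores": {
   "$ref": "#/$defs/ScoreBlock"
  },
  "alerts": {
   "items": {
    "$ref": "#/$defs/AlertDisplay"
   },
   "title": "Alerts",
   "type": "array"
  },
  "suppressed": {
   "items": {
    "type": "string"
   },
   "title": "Suppressed",
   "type": "array"
  },
  "errors": {
   "items": {
    "additionalProperties": true,
    "type": "object"
   },
   "title": "Errors",
   "type": "array"
  },
  "trace": {
   "items": {
    "$ref": "#/$defs/TraceRecord"
   },
   "title": "Trace",
   "type": "array"
  },
  "engine_version": {
   "default": "0.1.0",
   "title": "Engine Version",
   "type": "string"
  },
  "kb_version": {
   "default": "",
   "title": "Kb Version",
   "type": "string"
  }
 },
 "required": [
  "status"
 ],
 "title": "Evaluation response",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}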