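{
 "$defs": {
  "ConceptRef": {
   "description": "Reference to a canonical concept (IRI-style id plus display label).",
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "label": {
     "minLength": 1,
     "title": "Label",
     "type": "string"
    }
   },
   "required": [
    "id",
    "label"
   ],
   "title": "ConceptRef",
   "type": "object"
  },
  "LocalCode": {
   "description": "A concept expressed in a local vocabulary, awaiting mapping.",
   "properties": {
    "code": {
     "minLength": 1,
     "title": "Code",
     "type": "string"
    },
    "vocabulary": {
     "minLength": 1,
     "title": "Vocabulary",
     "type": "string"
    }
   },
   "required": [
    "code",
    "vocabulary"
   ],
   "title": "LocalCode",
   "type": "object"
  },
  "_WireLab": {
   "additionalProperties": false,
   "properties": {
    "test": {
     "anyOf": [
      {
       "$ref": "#/$defs/ConceptRef"
      },
      {
       "$ref": "#/$defs/LocalCode"
      }
     ],
     "title": "Test"
    },
    "value": {
     "title": "Value",
     "type": "number"
    },
    "unit": {
     "minLength": 1,
     "title": "Unit",
     "type": "string"
    },
    "observed_at": {
     "format": "date-time",
     "title": "Observed At",
     "type": "string"
    }
   },
   "required": [
    "test",
    "value",
    "unit",
    "observed_at"
   ],
   "title": "_WireLab",
   "type": "object"
  },
  "_WireOrder": {
   "additionalProperties": false,
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "vmp": {
     "anyOf": [
      {
       "$ref": "#/$defs/ConceptRef"
      },
      {
       "$ref": "#/$defs/LocalCode"
      }
     ],
     "title": "Vmp"
    },
    "ingredient": {
     "anyOf": [
      {
       "$ref": "#/$defs/ConceptRef"
      },
      {
       "$ref": "#/$defs/LocalCode"
      }
     ],
     "title": "Ingredient"
    },
    "form_route": {
     "anyOf": [
      {
       "$ref": "#/$defs/ConceptRef"
      },
      {
       "$ref": "#/$defs/LocalCode"
      }
     ],
     "title": "Form Route"
    },
    "dose": {
     "exclusiveMinimum": 0,
     "title": "Dose",
     "type": "number"
    },
    "unit": {
     "minLength": 1,
     "title": "Unit",
     "type": "string"
    },
    "frequency": {
     "anyOf": [
      {
       "$ref": "#/$defs/ConceptRef"
      },
      {
       "$ref": "#/$defs/LocalCode"
      }
     ],
     "title": "Frequency"
    },
    "prn": {
     "default": false,
     "title": "Prn",
     "type": "boolean"
    },
    "route": {
     "default": "oral",
     "title": "Route",
     "type": "string"
    }
   },
   "required": [
    "id",
    "vmp",
    "ingredient",
    "form_route",
    "dose",
    "unit",
    "frequency"
   ],
   "title": "_WireOrder",
   "type": "object"
  },
  "_WirePatient": {
   "additionalProperties": false,
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "age": {
     "minimum": 0,
     "title": "Age",
     "type": "integer"
    }
   },
   "required": [
    "id",
    "age"
   ],
   "title": "_WirePatient",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "patient": {
   "$ref": "#/$defs/_WirePatient"
  },
  "orders": {
   "items": {
    "$ref": "#/$defs/_WireOrder"
   },
   "title": "Orders",
   "type": "array"
  },
  "labs": {
   "items": {
    "$ref": "#/$defs/_WireLab"
   },
   "title": "Labs",
   "type": "array"
  }
 },
 "required": [
  "patient"
 ],
 "title": "Patient evaluation request",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}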