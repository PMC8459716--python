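{
 "$defs": {
  "DrawingRecord": {
   "description": "One distributed finding drawn on one template view.\n\n``polygons`` is a list of closed polygons, each an ordered vertex list\nof (x, y) pairs in normalized [0, 1] x [0, 1] template coordinates.",
   "properties": {
    "sign": {
     "enum": [
      "spontaneous_pain",
      "allodynia",
      "superficial_hyperalgesia",
      "deep_hyperalgesia",
      "superficial_skin_resistance",
      "muscle_resistance",
      "defense",
      "asymmetric_hyperhidrosis",
      "piloerection",
      "vasomotor_changes",
      "zoster",
      "passive_movement_resistance"
     ],
     "title": "Sign",
     "type": "string"
    },
    "view": {
     "enum": [
      "front",
      "back"
     ],
     "title": "View",
     "type": "string"
    },
    "polygons": {
     "items": {
      "items": {
       "maxItems": 2,
       "minItems": 2,
       "prefixItems": [
        {
         "type": "number"
        },
        {
         "type": "number"
        }
       ],
       "type": "array"
      },
      "type": "array"
     },
     "title": "Polygons",
     "type": "array"
    }
   },
   "required": [
    "sign",
    "view",
    "polygons"
   ],
   "title": "DrawingRecord",
   "type": "object"
  },
  "LateralizedFinding": {
   "properties": {
    "finding": {
     "enum": [
      "mydriasis",
      "glossy_eye",
      "eyelid_separation",
      "tense_facial_muscles",
      "asymmetric_posture",
      "reduced_respiration"
     ],
     "title": "Finding",
     "type": "string"
    },
    "side": {
     "enum": [
      "left",
      "right"
     ],
     "title": "Side",
     "type": "string"
    }
   },
   "required": [
    "finding",
    "side"
   ],
   "title": "LateralizedFinding",
   "type": "object"
  },
  "PatientRecord": {
   "description": "One patient: drawings, lateralized findings, symptoms, diagnosis.\n\nDemographics are optional; the statistics only need ``id`` and\n``organ``.",
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "organ": {
     "enum": [
      "heart",
      "lungs",
      "stomach",
      "liver_gallbladder",
      "kidneys_ureters",
      "other",
      "multi",
      "undiagnosed"
     ],
     "title": "Organ",
     "type": "string"
    },
    "drawings": {
     "items": {
      "$ref": "#/$defs/DrawingRecord"
     },
     "title": "Drawings",
     "type": "array"
    },
    "lateralized": {
     "items": {
      "$ref": "#/$defs/LateralizedFinding"
     },
     "title": "Lateralized",
     "type": "array"
    },
    "symptoms": {
     "items": {
      "enum": [
       "nausea",
       "vomiting",
       "constipation",
       "diarrhea",
       "meteorism",
       "urinary_retention"
      ],
      "type": "string"
     },
     "title": "Symptoms",
     "type": "array"
    },
    "age": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Age"
    },
    "sex": {
     "anyOf": [
      {
       "enum": [
        "female",
        "male"
       ],
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Sex"
    }
   },
   "required": [
    "id",
    "organ"
   ],
   "title": "PatientRecord",
   "type": "object"
  }
 },
 "description": "A list of patient records plus provenance metadata.",
 "properties": {
  "patients": {
   "items": {
    "$ref": "#/$defs/PatientRecord"
   },
   "title": "Patients",
   "type": "array"
  },
  "meta": {
   "additionalProperties": true,
   "title": "Meta",
   "type": "object"
  }
 },
 "required": [
  "patients"
 ],
 "title": "Cohort",
 "type": "object"
}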