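{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cryosperm feature table row",
  "description": "One semen sample: donor and treatment metadata, donor age, CASA kinematics, bioenergetic/redox/DNA-integrity markers, and holotomography region volumes.",
  "type": "object",
  "required": [
    "donor_id", "treatment", "age",
    "tm", "pm", "vcl", "vsl", "vap",
    "mmp", "lpo", "ros", "no",
    "tunel_dfi", "scsa_dfi",
    "vol_whole", "vol_mid", "vol_nuc"
  ],
  "properties": {
    "donor_id": {"type": "string", "description": "donor label, e.g. #3 .. #12"},
    "treatment": {
      "type": "string",
      "enum": ["Fresh", "CTRL-", "CTRL+", "Matcha", "Spirulina", "Horseradish", "Quercetin"]
    },
    "age": {"type": "number", "minimum": 0, "description": "donor age, years"},
    "tm": {"type": "number", "minimum": 0, "maximum": 100, "description": "total motility, %"},
    "pm": {"type": "number", "minimum": 0, "maximum": 100, "description": "progressive motility, %"},
    "vcl": {"type": "number", "minimum": 0, "description": "curvilinear velocity, um/s"},
    "vsl": {"type": "number", "minimum": 0, "description": "straight-line velocity, um/s"},
    "vap": {"type": "number", "minimum": 0, "description": "average path velocity, um/s"},
    "mmp": {"type": "number", "minimum": 0, "description": "mitochondrial membrane potential, ratio a.u."},
    "lpo": {"type": "number", "minimum": 0, "description": "lipid peroxidation, fluorescence a.u."},
    "ros": {"type": "number", "minimum": 0, "description": "reactive oxygen species, fluorescence a.u."},
    "no": {"type": "number", "minimum": 0, "description": "nitric oxide, fluorescence a.u."},
    "tunel_dfi": {"type": "number", "minimum": 0, "maximum": 100, "description": "TUNEL DNA fragmentation index, %"},
    "scsa_dfi": {"type": "number", "minimum": 0, "maximum": 100, "description": "SCSA DNA fragmentation index, %"},
    "vol_whole": {"type": "number", "exclusiveMinimum": 0, "description": "whole-cell volume, um^3"},
    "vol_mid": {"type": "number", "exclusiveMinimum": 0, "description": "post-acrosomal/midpiece volume, um^3 (<= vol_whole)"},
    "vol_nuc": {"type": "number", "exclusiveMinimum": 0, "description": "nuclear-region volume, um^3 (<= vol_whole)"}
  }
}
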