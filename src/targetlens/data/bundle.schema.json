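{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "targetlens single-target knowledge bundle",
  "type": "object",
  "required": ["gene_name"],
  "properties": {
    "gene_name": {"type": "string", "minLength": 1},
    "uniprot_id": {"type": ["string", "null"]},
    "structures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["structure_id"],
        "properties": {
          "structure_id": {"type": "string"},
          "method": {"type": "string"},
          "resolution": {"type": ["number", "null"], "exclusiveMinimum": 0},
          "coverage": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "pockets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["structure_id", "pocket_index", "ligandability_score"],
        "properties": {
          "structure_id": {"type": "string"},
          "pocket_index": {"type": "integer", "minimum": 1},
          "ligandability_score": {"type": "number", "minimum": 0, "maximum": 1},
          "volume": {"type": ["number", "null"], "minimum": 0},
          "alpha_sphere_count": {"type": ["integer", "null"], "minimum": 0}
        }
      }
    },
    "pocket_similarity": {
      "type": ["object", "null"],
      "required": ["homolog_id", "sequence_identity"],
      "properties": {
        "homolog_id": {"type": "string"},
        "sequence_identity": {"type": "number", "minimum": 0, "maximum": 100},
        "pockets": {"$ref": "#/properties/pockets"}
      }
    },
    "bioactivities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ligand_id", "target_id", "activity_type", "value"],
        "properties": {
          "ligand_id": {"type": "string"},
          "target_id": {"type": "string"},
          "activity_type": {
            "enum": ["Ki", "Kd", "IC50", "EC50", "percent_inhibition", "ADME", "other"]
          },
          "value": {"type": "number"},
          "properties": {"type": "object", "additionalProperties": {"type": "number"}}
        }
      }
    },
    "disease_associations": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "number", "minimum": 0, "maximum": 1}]
      }
    },
    "genetic_associations": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "number", "minimum": 0, "maximum": 1}]
      }
    },
    "expression": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "label": {"enum": ["High", "Medium", "Low", "Not observed"]},
          "code": {"enum": [3, 2, 1, 0]}
        }
      }
    },
    "genotypes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["genotype"],
        "properties": {
          "genotype": {"type": "string"},
          "phenotypes": {"type": "array", "items": {"type": "string"}},
          "lethal": {"type": "boolean"},
          "abnormal": {"type": "boolean"}
        }
      }
    },
    "isoform_count": {"type": "integer", "minimum": 0},
    "variant_count": {"type": "integer", "minimum": 0},
    "publications": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "date": {"type": ["string", "null"], "format": "date"},
          "title": {"type": "string"}
        }
      }
    },
    "safety_flags": {"type": "array", "items": {"type": "string"}},
    "antibody_count": {"type": "integer", "minimum": 0}
  }
}
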