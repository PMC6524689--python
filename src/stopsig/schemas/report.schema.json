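{
  "$defs": {
    "AnovaEffectReport": {
      "properties": {
        "F": {
          "title": "F",
          "type": "number"
        },
        "df1": {
          "title": "Df1",
          "type": "integer"
        },
        "df2": {
          "title": "Df2",
          "type": "integer"
        },
        "p": {
          "title": "P",
          "type": "number"
        },
        "partial_eta_sq": {
          "title": "Partial Eta Sq",
          "type": "number"
        }
      },
      "required": [
        "F",
        "df1",
        "df2",
        "p",
        "partial_eta_sq"
      ],
      "title": "AnovaEffectReport",
      "type": "object"
    },
    "BayesFactorReport": {
      "properties": {
        "bf10": {
          "title": "Bf10",
          "type": "number"
        },
        "prior_location": {
          "title": "Prior Location",
          "type": "number"
        },
        "prior_scale": {
          "title": "Prior Scale",
          "type": "number"
        },
        "side": {
          "title": "Side",
          "type": "string"
        },
        "numerical_error": {
          "title": "Numerical Error",
          "type": "number"
        }
      },
      "required": [
        "bf10",
        "prior_location",
        "prior_scale",
        "side",
        "numerical_error"
      ],
      "title": "BayesFactorReport",
      "type": "object"
    },
    "ContrastReport": {
      "properties": {
        "groups": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Groups",
          "type": "object"
        },
        "d": {
          "title": "D",
          "type": "number"
        },
        "d_ci": {
          "items": {
            "type": "number"
          },
          "title": "D Ci",
          "type": "array"
        },
        "t": {
          "title": "T",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        },
        "p": {
          "title": "P",
          "type": "number"
        },
        "side": {
          "title": "Side",
          "type": "string"
        },
        "bayes_factors": {
          "items": {
            "$ref": "#/$defs/BayesFactorReport"
          },
          "title": "Bayes Factors",
          "type": "array"
        },
        "robustness": {
          "items": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Robustness",
          "type": "array"
        }
      },
      "required": [
        "groups",
        "d",
        "d_ci",
        "t",
        "df",
        "p",
        "side",
        "bayes_factors",
        "robustness"
      ],
      "title": "ContrastReport",
      "type": "object"
    }
  },
  "additionalProperties": true,
  "properties": {
    "group_order": {
      "items": {
        "type": "string"
      },
      "title": "Group Order",
      "type": "array"
    },
    "effectors": {
      "items": {
        "type": "string"
      },
      "title": "Effectors",
      "type": "array"
    },
    "conf_level": {
      "title": "Conf Level",
      "type": "number"
    },
    "anova": {
      "additionalProperties": {
        "additionalProperties": {
          "$ref": "#/$defs/AnovaEffectReport"
        },
        "type": "object"
      },
      "title": "Anova",
      "type": "object"
    },
    "contrasts": {
      "additionalProperties": {
        "$ref": "#/$defs/ContrastReport"
      },
      "title": "Contrasts",
      "type": "object"
    },
    "correlations": {
      "additionalProperties": true,
      "title": "Correlations",
      "type": "object"
    },
    "slowing": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Slowing"
    }
  },
  "required": [
    "group_order",
    "effectors",
    "conf_level",
    "anova",
    "contrasts",
    "correlations"
  ],
  "title": "ReportModel",
  "type": "object"
}
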