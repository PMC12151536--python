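{
  "association": {
    "enhancers": {
      "fractions": {
        "high": 0.9024390244,
        "inactive": 0.9512195122,
        "low": 0.9756097561,
        "mid": 0.9756097561
      },
      "n_links": 283,
      "n_loop_supported": 5
    },
    "super_enhancers": {
      "fractions": {
        "high": 0.0,
        "inactive": 0.0,
        "low": 0.0,
        "mid": 0.0
      },
      "n_links": 0,
      "n_loop_supported": 0
    }
  },
  "colocalization": {
    "contrast": {
      "fisher_p": 0.0415912423,
      "note": "statistical contrast is an addition beyond raw percentages",
      "odds_ratio": 7.1111111111,
      "percent_difference": 44.7
    },
    "enhancer": {
      "n": 41,
      "n_coloc": 9,
      "percent": 22.0
    },
    "super_enhancer": {
      "n": 6,
      "n_coloc": 4,
      "percent": 66.7
    }
  },
  "enhancers": {
    "fraction_common": {
      "S1": 0.7321428571,
      "S2": 0.7321428571,
      "S3": 0.7321428571
    },
    "mode": "double_positive_union",
    "n_common": 41
  },
  "expression": {
    "bin_counts": {
      "high": 10,
      "inactive": 10,
      "low": 10,
      "mid": 10
    },
    "n_active": 30,
    "n_genes": 40
  },
  "perturb": {
    "multiplicity_fractions": {
      "multiplet": 0.2716666667,
      "none": 0.1866666667,
      "singlet": 0.5416666667
    },
    "n_cells": 600,
    "per_grna_singlets": {
      "NonTargeting": 61,
      "g1": 67,
      "g2": 76,
      "g3": 57,
      "g4": 64
    },
    "target_calls": [
      {
        "activated": true,
        "adjusted_p": 7.986e-06,
        "fold_change": 2.2375109397,
        "gene": "TGT1",
        "grna": "g1",
        "rank": 1
      },
      {
        "activated": false,
        "adjusted_p": 0.9306688682,
        "fold_change": 1.1531244828,
        "gene": "TGT2",
        "grna": "g2",
        "rank": 12
      },
      {
        "activated": false,
        "adjusted_p": 0.989250859,
        "fold_change": 0.9798594973,
        "gene": "TGT3",
        "grna": "g3",
        "rank": 53
      },
      {
        "activated": false,
        "adjusted_p": 0.8741331945,
        "fold_change": 1.1896308615,
        "gene": "TGT4",
        "grna": "g4",
        "rank": 10
      }
    ]
  },
  "provenance": {
    "config_hash": "8a11e3313603aa4c",
    "seed": 11,
    "tool": "regmap",
    "version": "0.1.0"
  },
  "samples": {
    "S1": {
      "n_h3k27ac": 91,
      "n_h3k4me1": 56,
      "n_putative_enhancers": 56,
      "n_super_enhancers": 6
    },
    "S2": {
      "n_h3k27ac": 91,
      "n_h3k4me1": 56,
      "n_putative_enhancers": 56,
      "n_super_enhancers": 6
    },
    "S3": {
      "n_h3k27ac": 91,
      "n_h3k4me1": 56,
      "n_putative_enhancers": 56,
      "n_super_enhancers": 6
    }
  },
  "super_enhancers": {
    "n_common": 6
  },
  "tf_activity": {
    "n_down_used": 60,
    "n_samples": 43,
    "n_up_used": 60,
    "p_value": 0.0142820946,
    "r": 0.3711198509,
    "target_gene": "TARGET"
  }
}
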