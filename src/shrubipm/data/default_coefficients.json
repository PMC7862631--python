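{
  "description": "Default fixed-effect coefficient set (estimate, standard error) for the four vital-rate regressions of Helianthemum squamatum (HS) and Lepidium subulatum (LS). Covariates are unstandardized: winter_temp in degC, spring_rain in mm, summer_wb in mm, intra/inter as cover fractions, blockB an indicator. Size and intercept terms are configuration, not part of this file. Reproduction models never include summer_wb (both species flower before June).",
  "species": {
    "HS": {
      "survival": {
        "blockB": {"estimate": 1.116, "se": 0.268},
        "intra": {"estimate": -0.481, "se": 0.359},
        "inter": {"estimate": -0.627, "se": 0.069},
        "winter_temp": {"estimate": 0.014, "se": 0.001},
        "spring_rain": {"estimate": 0.073, "se": 0.004},
        "summer_wb": {"estimate": -0.091, "se": 0.091}
      },
      "growth": {
        "blockB": {"estimate": -0.722, "se": 0.145},
        "intra": {"estimate": 0.454, "se": 0.170},
        "inter": {"estimate": 0.075, "se": 0.038},
        "winter_temp": {"estimate": -0.005, "se": 0.001},
        "spring_rain": {"estimate": -0.028, "se": 0.002},
        "summer_wb": {"estimate": -0.021, "se": 0.059}
      },
      "reproduction": {
        "blockB": {"estimate": -1.471, "se": 0.408},
        "intra": {"estimate": 0.872, "se": 0.500},
        "inter": {"estimate": 2.510, "se": 0.114},
        "winter_temp": {"estimate": -0.042, "se": 0.002},
        "spring_rain": {"estimate": -0.507, "se": 0.147}
      },
      "fecundity": {
        "blockB": {"estimate": -4.731, "se": 0.181},
        "intra": {"estimate": 0.154, "se": 0.102},
        "inter": {"estimate": -1.093, "se": 0.022},
        "winter_temp": {"estimate": 0.016, "se": 0.000},
        "spring_rain": {"estimate": 0.054, "se": 0.002},
        "summer_wb": {"estimate": 0.365, "se": 0.162}
      }
    },
    "LS": {
      "survival": {
        "blockB": {"estimate": 0.454, "se": 0.893},
        "intra": {"estimate": -2.030, "se": 0.611},
        "inter": {"estimate": -0.690, "se": 0.200},
        "winter_temp": {"estimate": 0.005, "se": 0.003},
        "spring_rain": {"estimate": 0.084, "se": 0.009}
      },
      "growth": {
        "intra": {"estimate": -0.363, "se": 0.312},
        "inter": {"estimate": 0.622, "se": 0.076},
        "winter_temp": {"estimate": -0.009, "se": 0.001},
        "spring_rain": {"estimate": -0.074, "se": 0.005}
      },
      "reproduction": {
        "intra": {"estimate": 4.511, "se": 1.922},
        "spring_rain": {"estimate": 0.270, "se": 0.412}
      },
      "fecundity": {
        "blockB": {"estimate": -1.432, "se": 0.458},
        "intra": {"estimate": -1.298, "se": 0.424},
        "inter": {"estimate": -0.532, "se": 0.072},
        "winter_temp": {"estimate": -0.002, "se": 0.001},
        "spring_rain": {"estimate": 0.158, "se": 0.007},
        "summer_wb": {"estimate": -0.170, "se": 0.304}
      }
    }
  }
}
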