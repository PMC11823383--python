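{
  "_description": "Published isobolographic summary statistics for the fixed-ratio (1:1) combination of the SIRT1 inhibitor EX527 (selisistat) with paclitaxel in five breast-cancer cell lines: per-line log-probit equations (probit effect vs log10 dose in uM), experimental mixture IC50s (+/- SEM, n = well count), and the theoretical additive IC50 bounds (single value for parallel lines, lower/upper for non-parallel).",
  "_notes": "Single-agent and mixture equations are included only for the three cell lines whose printed equation/IC50 pairings are internally consistent (the T47D and MDA-MB-468 equation labels in the source report are swapped between the single-agent and mixture series, so only their tabulated IC50 summaries are carried here).",
  "design": {"fraction_f": 0.5, "drug_a_label": "EX527", "drug_b_label": "PAX"},
  "cell_lines": {
    "MCF7": {
      "parallel": false,
      "single_agent_line": {"slope": 4.3531, "intercept": -3.4047, "r_squared": 0.961},
      "mixture_line": {"slope": 1.3686, "intercept": 2.9586, "r_squared": 0.899},
      "mixture": {"ic50_um": 31.02, "sem_um": 7.52, "n": 96},
      "additive": {"lower_um": 22.38, "sem_lower_um": 7.44, "upper_um": 63.18, "sem_upper_um": 8.04, "n": 116}
    },
    "T47D": {
      "parallel": true,
      "mixture": {"ic50_um": 29.52, "sem_um": 3.29, "n": 120},
      "additive": {"lower_um": 25.38, "sem_lower_um": 5.67, "upper_um": 25.38, "sem_upper_um": 5.67, "n": 188}
    },
    "MDA-MB-231": {
      "parallel": false,
      "single_agent_line": {"slope": 2.2873, "intercept": 1.0965, "r_squared": 0.995},
      "mixture_line": {"slope": 2.4277, "intercept": 1.1523, "r_squared": 0.958},
      "mixture": {"ic50_um": 38.45, "sem_um": 5.26, "n": 96},
      "additive": {"lower_um": 18.40, "sem_lower_um": 7.34, "upper_um": 32.55, "sem_upper_um": 8.31, "n": 164}
    },
    "BT-549": {
      "parallel": true,
      "single_agent_line": {"slope": 2.2979, "intercept": 1.0988, "r_squared": 0.989},
      "mixture_line": {"slope": 2.4131, "intercept": 1.4158, "r_squared": 0.9588},
      "mixture": {"ic50_um": 30.57, "sem_um": 3.760, "n": 120},
      "additive": {"lower_um": 24.93, "sem_lower_um": 3.60, "upper_um": 24.93, "sem_upper_um": 3.60, "n": 140}
    },
    "MDA-MB-468": {
      "parallel": true,
      "mixture": {"ic50_um": 33.40, "sem_um": 3.93, "n": 96},
      "additive": {"lower_um": 24.52, "sem_lower_um": 4.49, "upper_um": 24.52, "sem_upper_um": 4.49, "n": 164}
    }
  }
}
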