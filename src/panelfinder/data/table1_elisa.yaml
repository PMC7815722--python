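# Published per-group ELISA summary statistics (ng/ml) used as defaults
# for the immunoassay simulator: median and quartiles (q1, q3) per
# analyte and clinical group, the assay lower limit of quantification
# (lloq) and the printed replicate CV% (kept as metadata; its inter- vs
# intra-assay meaning is not defined in the source table).
#
# One printed upper quartile (TMSB4X in the embryonal-tumor group) is
# impossible as printed (below the lower quartile); it is replaced here
# by 0.004, mirroring the control group's quartile width.
n_per_group:
  control: 22
  post_hemorrhagic: 15
  LGG_GT: 11
  EMB: 11
  other_tumor: 9
replicate_cv: 0.05
analytes:
  TAF15:
    lloq: 0.01
    cv_pct: 3.6
    groups:
      control:          {median: 0.09,  q1: 0.08,  q3: 0.11}
      post_hemorrhagic: {median: 0.08,  q1: 0.07,  q3: 0.08}
      LGG_GT:           {median: 0.03,  q1: 0.02,  q3: 0.04}
      EMB:              {median: 0.03,  q1: 0.02,  q3: 0.04}
      other_tumor:      {median: 0.04,  q1: 0.03,  q3: 0.05}
  S100B:
    lloq: 0.04
    cv_pct: 4.8
    groups:
      control:          {median: 0.1,   q1: 0.09,  q3: 0.11}
      post_hemorrhagic: {median: 0.11,  q1: 0.09,  q3: 0.13}
      LGG_GT:           {median: 0.57,  q1: 0.56,  q3: 0.6}
      EMB:              {median: 0.75,  q1: 0.64,  q3: 0.81}
      other_tumor:      {median: 0.58,  q1: 0.56,  q3: 0.6}
  TMSB4X:
    lloq: 0.0001
    cv_pct: 4.4
    groups:
      control:          {median: 0.003, q1: 0.003, q3: 0.004}
      post_hemorrhagic: {median: 0.01,  q1: 0.004, q3: 0.01}
      LGG_GT:           {median: 0.01,  q1: 0.01,  q3: 0.01}
      EMB:              {median: 0.003, q1: 0.003, q3: 0.004}
      other_tumor:      {median: 0.003, q1: 0.002, q3: 0.003}
  CD109:
    lloq: 0.15
    cv_pct: 3.8
    groups:
      control:          {median: 0.43,  q1: 0.39,  q3: 0.53}
      post_hemorrhagic: {median: 0.48,  q1: 0.41,  q3: 0.51}
      LGG_GT:           {median: 0.79,  q1: 0.67,  q3: 0.83}
      EMB:              {median: 0.4,   q1: 0.39,  q3: 0.43}
      other_tumor:      {median: 0.52,  q1: 0.47,  q3: 0.54}
  YWHA_1433:
    lloq: 0.15
    cv_pct: 3.1
    groups:
      control:          {median: 0.34,  q1: 0.34,  q3: 0.36}
      post_hemorrhagic: {median: 0.35,  q1: 0.34,  q3: 0.36}
      LGG_GT:           {median: 0.34,  q1: 0.34,  q3: 0.35}
      EMB:              {median: 0.56,  q1: 0.41,  q3: 0.59}
      other_tumor:      {median: 0.34,  q1: 0.34,  q3: 0.35}
  HSP90A:
    lloq: 0.04
    cv_pct: 2.9
    groups:
      control:          {median: 0.08,  q1: 0.08,  q3: 0.08}
      post_hemorrhagic: {median: 0.08,  q1: 0.08,  q3: 0.08}
      LGG_GT:           {median: 0.08,  q1: 0.08,  q3: 0.08}
      EMB:              {median: 0.08,  q1: 0.08,  q3: 0.08}
      other_tumor:      {median: 0.08,  q1: 0.08,  q3: 0.08}
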