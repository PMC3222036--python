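seed: 0
contextual_shift: 0.0
censor_threshold_pct: null
censor_drop_p: 0.0
strata:
- name: benchmark
  series: benchmark
  arm_role: benchmark
  k: 45
  mu_pct: 22.1
  tau2: 0.34
  denom_median: 264
  denom_q1: 83
  denom_q3: 567
  bronchoscopic_p: 0.5111111111111111
  trauma_mean: 0.12
  trauma_concentration: 2.0
  mv_lt90_p: 0.1111111111111111
  quality_p: null
  duplex_p: 0.0
  european_p: 0.6222222222222222
  year_range:
  - 1990
  - 2000
  source_review: synthetic
- name: nonanti-control
  series: non_antimicrobial
  arm_role: control
  k: 35
  mu_pct: 20.4
  tau2: 0.41
  denom_median: 54
  denom_q1: 29
  denom_q3: 92
  bronchoscopic_p: 0.14285714285714285
  trauma_mean: 0.15
  trauma_concentration: 2.0
  mv_lt90_p: 0.05714285714285714
  quality_p: 0.45714285714285713
  duplex_p: 0.0
  european_p: 0.5428571428571428
  year_range:
  - 1994
  - 2000
  source_review: synthetic
- name: nonanti-intervention
  series: non_antimicrobial
  arm_role: intervention
  k: 35
  mu_pct: 17.1
  tau2: 0.35
  denom_median: 54
  denom_q1: 29
  denom_q3: 92
  bronchoscopic_p: 0.14285714285714285
  trauma_mean: 0.15
  trauma_concentration: 2.0
  mv_lt90_p: 0.05714285714285714
  quality_p: 0.45714285714285713
  duplex_p: 0.0
  european_p: 0.5428571428571428
  year_range:
  - 1994
  - 2000
  source_review: synthetic
- name: sdd-control
  series: sdd
  arm_role: control
  k: 33
  mu_pct: 35.7
  tau2: 0.63
  denom_median: 57
  denom_q1: 33
  denom_q3: 130
  bronchoscopic_p: 0.24242424242424243
  trauma_mean: 0.34
  trauma_concentration: 2.0
  mv_lt90_p: 0.12121212121212122
  quality_p: 0.12121212121212122
  duplex_p: 0.12121212121212122
  european_p: 0.9090909090909091
  year_range:
  - 1991
  - 1997
  source_review: synthetic
- name: sdd-intervention
  series: sdd
  arm_role: intervention
  k: 34
  mu_pct: 16.0
  tau2: 0.59
  denom_median: 57
  denom_q1: 33
  denom_q3: 130
  bronchoscopic_p: 0.24242424242424243
  trauma_mean: 0.34
  trauma_concentration: 2.0
  mv_lt90_p: 0.12121212121212122
  quality_p: 0.12121212121212122
  duplex_p: 0.0
  european_p: 0.9090909090909091
  year_range:
  - 1991
  - 1997
  source_review: synthetic
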