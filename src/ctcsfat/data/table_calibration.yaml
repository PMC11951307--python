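# Default cohort calibration: arm-wise moments of the baseline covariates and
# per-vessel Agatston scores (synthetic approximation — means/SDs and
# proportions only; cross-covariate correlations are 0 unless configured).
# "pr_pos" / "pr_neg" are the positive-remodeling and non-remodeling arms.
covariates:
  male:                {kind: binary,     pr_pos: 0.737, pr_neg: 0.470}
  bmi:                 {kind: continuous, pr_pos: [28.6, 4.7],   pr_neg: [30.1, 5.9]}
  age:                 {kind: continuous, pr_pos: [60.5, 8.0],   pr_neg: [55.7, 9.6]}
  bmi_band_ge30:       {kind: binary,     pr_pos: 0.331, pr_neg: 0.438}
  age_band_60_75:      {kind: binary,     pr_pos: 0.557, pr_neg: 0.378}
  diabetes:            {kind: binary,     pr_pos: 0.124, pr_neg: 0.106}
  height_m:            {kind: continuous, pr_pos: [1.72, 0.09],  pr_neg: [1.69, 0.10]}
  weight_kg:           {kind: continuous, pr_pos: [84.1, 15.1],  pr_neg: [86.0, 18.9]}
  cigarettes_per_day:  {kind: continuous, pr_pos: [2.9, 6.6],    pr_neg: [2.8, 7.3], clip_min: 0.0}
  hypertension:        {kind: binary,     pr_pos: 0.403, pr_neg: 0.325}
  total_cholesterol:   {kind: continuous, pr_pos: [5.04, 1.94],  pr_neg: [5.02, 1.82]}
  hdl_cholesterol:     {kind: continuous, pr_pos: [0.92, 0.66],  pr_neg: [1.06, 0.70], clip_min: 0.1}
  chd_family_history:  {kind: binary,     pr_pos: 0.447, pr_neg: 0.441}
  systolic_bp:         {kind: continuous, pr_pos: [140.4, 21.5], pr_neg: [137.3, 25.0]}
  diastolic_bp:        {kind: continuous, pr_pos: [81.4, 12.0],  pr_neg: [81.1, 14.5]}
  chest_pain_anginal:  {kind: binary,     pr_pos: 0.734, pr_neg: 0.535}
  antiplatelet:        {kind: binary,     pr_pos: 0.839, pr_neg: 0.493}
  statin:              {kind: binary,     pr_pos: 0.800, pr_neg: 0.440}
  ace_inhibitor:       {kind: binary,     pr_pos: 0.242, pr_neg: 0.141}
  calcium_blocker:     {kind: binary,     pr_pos: 0.117, pr_neg: 0.084}
  nitrates:            {kind: binary,     pr_pos: 0.368, pr_neg: 0.198}
  betablocker:         {kind: binary,     pr_pos: 0.501, pr_neg: 0.277}
  hyperlipidemia:      {kind: binary,     pr_pos: 0.748, pr_neg: 0.537}

# Per-vessel log10(Agatston + 1) moments per arm; scores are drawn on the log
# scale (truncated at 0) and exponentiated, so the 12 derived score features
# stay mutually consistent.
agatston_log10:
  LM:  {pr_pos: [0.57, 0.84], pr_neg: [0.13, 0.43]}
  LAD: {pr_pos: [2.02, 0.75], pr_neg: [0.55, 0.87]}
  LCX: {pr_pos: [1.17, 1.03], pr_neg: [0.26, 0.63]}
  RCA: {pr_pos: [1.46, 1.10], pr_neg: [0.35, 0.71]}

# Ribbon HU-probability features carrying the fat-omics signal. Arm-wise
# moments are synthetic choices (no reference values exist): separations of
# roughly one pooled SD for the elevated-HU outer-ribbon features, smaller
# for the low-HU bins, matching the direction reported for remodeling
# (elevated HU probability higher in the PR arm).
fatomics:
  SR4_Pro_90_70:   {pr_pos: [0.16, 0.06], pr_neg: [0.09, 0.05]}
  SR5_Pro_90_70:   {pr_pos: [0.14, 0.06], pr_neg: [0.08, 0.05]}
  SR3_Pro_150_130: {pr_pos: [0.10, 0.04], pr_neg: [0.13, 0.05]}
  SR3_Pro_170_150: {pr_pos: [0.07, 0.03], pr_neg: [0.09, 0.04]}
  SR4_Pro_110_90:  {pr_pos: [0.15, 0.05], pr_neg: [0.12, 0.05]}
  SR2_Pro_130_110: {pr_pos: [0.13, 0.05], pr_neg: [0.13, 0.05]}
  SL1_Pro_90_70:   {pr_pos: [0.12, 0.05], pr_neg: [0.10, 0.05]}
  SL4_Pro_170_150: {pr_pos: [0.08, 0.04], pr_neg: [0.08, 0.04]}
  mean_thickness_mm: {pr_pos: [5.6, 1.6], pr_neg: [4.9, 1.5], clip_min: 0.5}
  volume_mm3:      {pr_pos: [130000.0, 48000.0], pr_neg: [110000.0, 45000.0], clip_min: 5000.0}

# Event-time model for MACE: exponential baseline hazard multiplied by
# exp(log_hr) in the PR arm; uniform censoring over the follow-up window.
hazard:
  baseline_rate_per_year: 0.03
  log_hr: 1.8718    # log(6.5), the actual-PR hazard ratio
  follow_up_years: 5.0
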