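# Published condition statistics of the stimulus-response calcium-imaging
# study, re-expressed as generative preset parameters. Location parameters
# (mu_*, responder_frac) are the reported group means / doubling
# percentages; reported_sem carries the printed standard errors (metadata
# only, never used in generation). Values marked "not reported" were chosen
# once as plausible defaults on the scale of the neighbouring conditions.
defaults:
  sd_peak_cell: 0.6        # per-cell amplitude SD (not constrained by the report)
  nonresponder_mu: 1.3     # sub-doubling component mean
  nonresponder_sd: 0.15
  sd_iono_cell: 0.6
  f0: 1000.0               # baseline counts
  noise_sd: 10.0           # additive noise, 1% of F0
  bleach_rate: 0.0         # no bleach correction is applied downstream
  background_level: 50.0
  n_cells_per_replicate: 50
  n_replicates: 3          # three independent setups per line
  n_lines: 2               # two cell lines per diagnosis group

conditions:
  # ---- pluripotent stage, ATP ------------------------------------------
  - group: ASD
    stage: iPSC
    stimulus: ATP
    mu_peak: 4.23          # reported mean max receptor-mediated fold
    mu_ttp: 82.59          # reported mean time to max, seconds
    responder_frac: 1.0    # responses described as homogeneous; no doubling % reported
    mu_iono_peak: 3.60     # reported mean max ionomycin fold
    mu_iono_ttp: 50.0      # not reported at this stage
    reported_sem: {max_rmr_fold: 0.085, time_to_max_rmr: 2.45, max_iono_fold: 0.081}
  - group: control
    stage: iPSC
    stimulus: ATP
    mu_peak: 3.71
    mu_ttp: 49.87
    responder_frac: 1.0
    mu_iono_peak: 3.89
    mu_iono_ttp: 50.0      # not reported at this stage
    reported_sem: {max_rmr_fold: 0.085, time_to_max_rmr: 1.91, max_iono_fold: 0.10}

  # ---- 1-week differentiated neurons, KCl ------------------------------
  - group: ASD
    stage: Diff1wk
    stimulus: KCl
    mu_peak: 2.55
    mu_ttp: 15.57
    responder_frac: 0.5737   # reported doubling percentage / 100
    mu_iono_peak: 2.80       # "no significant differences" only; value not reported
    mu_iono_ttp: 50.0        # not reported
    reported_sem: {max_rmr_fold: 0.14, time_to_max_rmr: 6.88, responder_percent: 6.33}
  - group: control
    stage: Diff1wk
    stimulus: KCl
    mu_peak: 2.20
    mu_ttp: 36.88
    responder_frac: 0.4230
    mu_iono_peak: 2.80       # not reported
    mu_iono_ttp: 50.0        # not reported
    reported_sem: {max_rmr_fold: 0.13, time_to_max_rmr: 3.21, responder_percent: 6.85}

  # ---- 1-week differentiated neurons, ATP ------------------------------
  - group: ASD
    stage: Diff1wk
    stimulus: ATP
    mu_peak: 1.58
    mu_ttp: 57.0
    responder_frac: 0.1363
    mu_iono_peak: 2.73
    mu_iono_ttp: 81.69
    reported_sem: {max_rmr_fold: 0.12, time_to_max_rmr: 7.78, responder_percent: 5.233,
                   max_iono_fold: 0.16, time_to_max_iono: 7.52}
  - group: control
    stage: Diff1wk
    stimulus: ATP
    mu_peak: 2.74
    mu_ttp: 27.62
    responder_frac: 0.85
    mu_iono_peak: 2.97
    mu_iono_ttp: 37.85
    reported_sem: {max_rmr_fold: 0.10, time_to_max_rmr: 6.30, responder_percent: 4.35,
                   max_iono_fold: 0.13, time_to_max_iono: 6.10}

  # ---- 4-week differentiated neurons, KCl ------------------------------
  - group: ASD
    stage: Diff4wk
    stimulus: KCl
    mu_peak: 3.30
    mu_ttp: 14.38          # no SEM reported for this time
    responder_frac: 0.8571
    mu_iono_peak: 3.28
    mu_iono_ttp: 36.16
    reported_sem: {max_rmr_fold: 0.13, responder_percent: 3.66,
                   max_iono_fold: 0.12, time_to_max_iono: 5.01}
  - group: control
    stage: Diff4wk
    stimulus: KCl
    mu_peak: 2.75
    mu_ttp: 20.97          # no SEM reported for this time
    responder_frac: 0.7522
    mu_iono_peak: 2.89
    mu_iono_ttp: 51.64
    reported_sem: {max_rmr_fold: 0.10, responder_percent: 4.061,
                   max_iono_fold: 0.10, time_to_max_iono: 4.46}

  # ---- 4-week differentiated neurons, ATP ------------------------------
  - group: ASD
    stage: Diff4wk
    stimulus: ATP
    mu_peak: 2.35
    mu_ttp: 38.0
    responder_frac: 0.5819
    mu_iono_peak: 2.97
    mu_iono_ttp: 45.35
    reported_sem: {max_rmr_fold: 0.14, time_to_max_rmr: 4.70, responder_percent: 3.71,
                   max_iono_fold: 0.14, time_to_max_iono: 4.52}
  - group: control
    stage: Diff4wk
    stimulus: ATP
    mu_peak: 2.88
    mu_ttp: 27.53
    responder_frac: 0.9078
    mu_iono_peak: 3.60
    mu_iono_ttp: 36.27
    reported_sem: {max_rmr_fold: 0.08, time_to_max_rmr: 2.75, responder_percent: 3.32,
                   max_iono_fold: 0.08, time_to_max_iono: 3.24}

  # ---- 4-week differentiated neurons, DHPG -----------------------------
  - group: ASD
    stage: Diff4wk
    stimulus: DHPG
    mu_peak: 2.68
    mu_ttp: 14.07
    responder_frac: 0.5957
    mu_iono_peak: 3.22
    mu_iono_ttp: 33.31
    reported_sem: {max_rmr_fold: 0.14, time_to_max_rmr: 1.60, responder_percent: 5.06,
                   max_iono_fold: 0.15, time_to_max_iono: 3.40}
  - group: control
    stage: Diff4wk
    stimulus: DHPG
    mu_peak: 2.14
    mu_ttp: 25.86
    responder_frac: 0.5113
    mu_iono_peak: 2.81
    mu_iono_ttp: 53.15
    reported_sem: {max_rmr_fold: 0.08, time_to_max_rmr: 0.12, responder_percent: 5.32,
                   max_iono_fold: 0.12, time_to_max_iono: 4.94}
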