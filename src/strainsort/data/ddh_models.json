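{
  "ggdc2-logitlog-synthetic-v1": {
    "comment": "SYNTHETIC coefficient set: logistic map from formula-2 genome distance d to the DDH scale, logit(ddh/100) = intercept + slope * ln(d). The original GGDC regression coefficients are not redistributed here; this set was least-squares calibrated against publicly reported paired (ANI, dDDH) values for Pseudomonas genome comparisons, approximating d by (100-ANI)/100. It reproduces each calibration pair within ~1.3 points and places the conventional 70% species boundary at d = 0.0377 (ANI ~ 96.2%). Override via genome_similarity.DdhModel for sensitivity analyses.",
    "intercept": -3.2576476485896855,
    "slope_log_distance": -1.2522419407894818
  }
}
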