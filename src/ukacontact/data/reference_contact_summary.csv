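# Published in vivo medial articular contact excursion summary for
# fixed-bearing UKA during stance, single-leg lunge and sit-to-stand,
# on the representative 43 x 26.5 mm polyethylene insert.
# Columns: per-activity cross-subject mean and SD of the per-trial average
# and range of the contact coordinate; mm and normalized (% of insert
# length for AP, width for ML).  Convention: anterior(+), medial(+).
activity,ap_avg_mm,ap_avg_sd,ap_avg_pct,ap_avg_pct_sd,ap_range_mm,ap_range_sd,ap_range_pct,ap_range_pct_sd,ml_avg_mm,ml_avg_sd,ml_avg_pct,ml_avg_pct_sd,ml_range_mm,ml_range_sd,ml_range_pct,ml_range_pct_sd
stance,5.2,2.7,12.0,6.2,6.0,1.6,13.9,3.7,1.8,1.6,6.8,6.2,1.9,0.6,7.5,2.3
lunge,1.0,2.4,2.4,5.5,7.9,2.7,18.5,6.4,0.9,1.5,3.3,5.6,2.4,1.3,9.2,5.2
sit_to_stand,2.1,3.3,4.9,7.6,8.6,2.6,19.9,6.0,1.4,1.4,5.5,5.5,2.2,1.2,8.3,4.5
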