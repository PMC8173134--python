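# In vitro wear-region / stress-distribution reference centers for medial
# fixed-bearing UKA polyethylene inserts, mapped onto the representative
# 43 x 26.5 mm insert.  Coordinates relative to the insert centroid,
# anterior(+) / medial(+).  "aggregate" is the pooled center used for the
# in vivo vs in vitro offset comparison (mm values as printed in the
# summary literature; percentages of insert length / width).
centers:
  - label: in_vitro_aggregate
    ap_mm: -0.5
    ml_mm: 0.7
    ap_pct: -1.1
    ml_pct: 2.6
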