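sample,live_weight_kg,carcass_weight_kg,dressing_pct,ribeye_area_cm2,marbling_grade
STH1,29.25,13.25,45.30,12.14,1.5
STH2,26.68,12.05,45.16,10.62,1.5
STH3,31.75,13.75,43.31,11.78,1.0
STH4,27.60,12.85,46.56,12.02,2.0
STH5,28.00,13.15,46.96,11.72,1.5
STH6,27.20,12.45,45.77,12.28,2.0
SFK x STH1,38.65,19.35,50.06,13.45,2.5
SFK x STH2,39.25,19.45,49.55,14.74,2.0
SFK x STH3,44.60,23.25,52.13,14.44,3.0
SFK x STH4,40.05,21.75,54.31,15.68,3.5
SFK x STH5,42.65,21.25,49.82,13.06,3.0
SFK x STH6,39.45,20.85,52.85,14.75,2.0
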