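subject_id,rater_id,laterality,eye_width_mm,mrd1_mm,peak_temporal_offset_mm,peak_height_mm,fissure_obliquity_deg,mpld_0_mm,mpld_15_mm,mpld_30_mm,mpld_45_mm,mpld_60_mm,mpld_75_mm,mpld_90_mm,mpld_105_mm,mpld_120_mm,mpld_135_mm,mpld_150_mm,mpld_165_mm,mpld_180_mm,ratio_105_75,ratio_120_60,ratio_135_45,ratio_150_30,ratio_165_15,ratio_180_0,ratio_total,ratio_total_definition
F001,,OD,22.5,3.19,3.8,3.7,9.44,6.56,4.8,3.86,3.36,3.11,3.06,3.19,3.52,4.15,5.23,6.99,9.32,11.14,1.15,1.33,1.56,1.81,1.94,1.7,1.58,mean_of_pairs
F002,,OD,23.33,4.11,2.26,4.32,11.05,7.6,5.96,4.97,4.4,4.09,4.0,4.11,4.42,4.98,5.89,7.26,9.15,11.34,1.1,1.22,1.34,1.46,1.54,1.49,1.36,mean_of_pairs
F003,,OD,23.14,4.39,0.74,4.41,10.81,8.39,6.8,5.74,5.04,4.62,4.41,4.39,4.56,4.95,5.64,6.75,8.48,11.08,1.03,1.07,1.12,1.18,1.25,1.32,1.16,mean_of_pairs
M001,,OD,23.28,3.05,2.73,3.24,3.6,8.75,5.87,4.39,3.61,3.2,3.03,3.05,3.26,3.71,4.57,6.11,8.64,11.35,1.07,1.16,1.26,1.39,1.47,1.3,1.28,mean_of_pairs
M002,,OD,25.79,3.77,2.05,3.9,10.75,8.22,6.2,4.99,4.28,3.89,3.73,3.77,4.01,4.51,5.38,6.84,9.17,12.42,1.07,1.16,1.26,1.37,1.48,1.51,1.31,mean_of_pairs
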