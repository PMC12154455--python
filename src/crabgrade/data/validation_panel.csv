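specimen_id,sex,area_auto_cm2,fatness_auto_pct,grade_auto,area_manual_cm2,fatness_manual_pct,grade_manual
M-1,male,30.37,75.27,I,30.28,75.93,I
M-2,male,38.74,62.04,II,38.38,63.00,II
M-3,male,32.00,56.28,IV,32.47,55.43,IV
M-4,male,42.76,64.94,II,43.40,64.34,II
M-5,male,47.78,61.14,III,48.13,61.14,III
M-6,male,42.54,43.19,IV,43.01,42.81,IV
M-7,male,44.24,61.90,III,43.57,61.90,III
M-8,male,35.03,55.96,IV,35.66,57.11,IV
M-9,male,41.08,63.19,II,40.39,62.41,II
M-10,male,29.92,59.54,III,30.59,58.67,III
F-1,female,37.44,56.73,II,37.09,57.34,II
F-2,female,41.56,47.96,IV,41.67,47.22,IV
F-3,female,59.58,50.82,IV,59.15,50.33,IV
F-4,female,31.40,62.18,I,31.52,62.18,I
F-5,female,36.55,63.26,I,36.21,64.70,I
F-6,female,28.46,58.10,I,29.38,58.10,I
F-7,female,29.93,55.38,II,30.60,55.85,II
F-8,female,31.45,46.06,IV,30.62,45.48,IV
F-9,female,31.73,48.09,IV,32.47,47.45,IV
F-10,female,37.91,52.83,III,37.03,52.41,III
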