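compound	factor	level	yield_pct
gallic acid	methanol_pct	50	0.46
gallic acid	methanol_pct	70	0.52
gallic acid	methanol_pct	100	0.67
gallic acid	solid_liquid_ratio	1:50	0.69
gallic acid	solid_liquid_ratio	1:125	0.88
gallic acid	solid_liquid_ratio	1:250	0.89
gallic acid	time_min	15	0.26
gallic acid	time_min	30	0.77
gallic acid	time_min	60	0.73
emodin	methanol_pct	50	1.25
emodin	methanol_pct	70	1.42
emodin	methanol_pct	100	1.55
emodin	solid_liquid_ratio	1:50	1.23
emodin	solid_liquid_ratio	1:125	1.75
emodin	solid_liquid_ratio	1:250	1.77
emodin	time_min	15	0.37
emodin	time_min	30	1.88
emodin	time_min	60	1.68
THSG	methanol_pct	50	1.26
THSG	methanol_pct	70	1.32
THSG	methanol_pct	100	1.61
THSG	solid_liquid_ratio	1:50	1.18
THSG	solid_liquid_ratio	1:125	1.93
THSG	solid_liquid_ratio	1:250	1.69
THSG	time_min	15	0.79
THSG	time_min	30	1.78
THSG	time_min	60	1.86
EMG	methanol_pct	50	0.86
EMG	methanol_pct	70	1.46
EMG	methanol_pct	100	1.44
EMG	solid_liquid_ratio	1:50	0.43
EMG	solid_liquid_ratio	1:125	1.65
EMG	solid_liquid_ratio	1:250	1.44
EMG	time_min	15	0.73
EMG	time_min	30	1.42
EMG	time_min	60	1.22
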