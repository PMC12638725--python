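# Hand-transcribed copy of the published office-based (BMI) general-CVD
# point assignments, kept as an independent transcription check of the
# packaged resource. Bands are [lower, upper).
sex	variable	lower	upper	points
F	age	30	35	0
F	age	35	40	2
F	age	40	45	4
F	age	45	50	5
F	age	50	55	7
F	age	55	60	8
F	age	60	65	9
F	age	65	70	10
F	age	70	75	11
F	age	75	inf	12
F	bmi	0	25	0
F	bmi	25	30	1
F	bmi	30	inf	2
F	sbp_untreated	0	120	-3
F	sbp_untreated	120	130	0
F	sbp_untreated	130	140	1
F	sbp_untreated	140	150	2
F	sbp_untreated	150	160	4
F	sbp_untreated	160	inf	5
F	sbp_treated	0	120	-1
F	sbp_treated	120	130	2
F	sbp_treated	130	140	3
F	sbp_treated	140	150	5
F	sbp_treated	150	160	6
F	sbp_treated	160	inf	7
F	smoker	1	2	3
F	diabetes	1	2	4
M	age	30	35	0
M	age	35	40	2
M	age	40	45	5
M	age	45	50	6
M	age	50	55	8
M	age	55	60	10
M	age	60	65	11
M	age	65	70	12
M	age	70	75	14
M	age	75	inf	15
M	bmi	0	25	0
M	bmi	25	30	1
M	bmi	30	inf	2
M	sbp_untreated	0	120	-2
M	sbp_untreated	120	130	0
M	sbp_untreated	130	140	1
M	sbp_untreated	140	160	2
M	sbp_untreated	160	inf	3
M	sbp_treated	0	120	0
M	sbp_treated	120	130	2
M	sbp_treated	130	140	3
M	sbp_treated	140	160	4
M	sbp_treated	160	inf	5
M	smoker	1	2	4
M	diabetes	1	2	3
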