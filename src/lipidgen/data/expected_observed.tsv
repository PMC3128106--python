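trait	population	n_tests	n_observed	n_expected	p_printed
HDL-C	AA	23	11	17.3	0.01
HDL-C	AI	20	9	14.4	0.01
HDL-C	MAH	23	13	13.8	0.83
LDL-C	AA	18	11	14.7	0.03
LDL-C	AI	14	10	11.9	0.15
LDL-C	MAH	18	10	10.6	0.81
lnTG	AA	14	8	11.9	0.01
lnTG	AI	13	10	8.4	0.56
lnTG	MAH	14	12	10.4	0.54
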