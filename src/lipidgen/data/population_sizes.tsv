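trait	population	n_max
HDL-C	EA	25167
HDL-C	AA	10436
HDL-C	AI	6134
HDL-C	MAH	3371
LDL-C	EA	21986
LDL-C	AA	9328
LDL-C	AI	6144
LDL-C	MAH	2532
lnTG	EA	24258
lnTG	AA	9844
lnTG	AI	6157
lnTG	MAH	2973
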