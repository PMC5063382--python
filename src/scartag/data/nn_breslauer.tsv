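stack	dH_kcal_per_mol	dS_cal_per_K_mol
AA	-9.1	-24.0
AC	-6.5	-17.3
AG	-7.8	-20.8
AT	-8.6	-23.9
CA	-5.8	-12.9
CC	-11.0	-26.6
CG	-11.9	-27.8
CT	-7.8	-20.8
GA	-5.6	-13.5
GC	-11.1	-26.7
GG	-11.0	-26.6
GT	-6.5	-17.3
TA	-6.0	-16.9
TC	-5.6	-13.5
TG	-5.8	-12.9
TT	-9.1	-24.0
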