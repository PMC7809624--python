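hsm	snp_id	locus	effect_allele	eaf	beta_adult	p_adult	n_adult	beta_age14	p_age14	n_age14	beta_age18	p_age18	n_age18
1	rs2158915	17q24.3/SOX9	G	0.35	-0.14	3.3e-23	12823	-0.054	9.9e-8	3550	-0.051	3.3e-6	3175
1	rs1243579	14q32.13/GSC	G	0.15	0.13	1.1e-13	12823	0.034	0.01	3550	0.024	0.086	3175
1	rs10743612	12p11.22/KLHL42-PTHLH	A	0.24	0.08	2.4e-8	12823	0.05	1.1e-5	3550	0.036	0.003	3175
1	rs73197346	21q22.12/RUNX1-MIR802	C	0.14	-0.10	1.5e-7	12823	-0.054	2.4e-4	3550	-0.035	0.026	3175
1	rs59341143	4p15.33/NKX3-2	C	0.15	0.08	2.3e-6	12823	0.023	0.102	3550	0.025	0.093	3175
2	rs1966265	5q35.2/FGFR4	T	0.38	0.13	2.3e-16	12823	0.051	0.018	3550	0.072	0.003	3175
2	rs6537291	4q31.21/HHIP	A	0.38	-0.079	4.2e-9	12823	-0.063	0.001	3550	-0.069	0.001	3175
2	rs1885245	9q33.1/ASTN2	G	0.40	0.075	4.4e-8	12823	0.044	0.019	3550	0.013	0.545	3175
5	rs2158915	17q24.3/SOX9	G	0.35	-0.093	8.7e-12	12823	-0.072	1.6e-4	3550	-0.10	2.7e-6	3175
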