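# RNA dinucleotide physicochemical property table (11 properties).
# Structural base-step parameters (shift/slide/rise in Angstrom,
# tilt/roll/twist in degrees) compiled from published A-form RNA averages;
# stacking energies (kcal/mol) from published base-stacking calculations;
# enthalpy (kcal/mol) and free energy at 37C (kcal/mol) from the Turner/Xia
# 1998 nearest-neighbor parameters, entropy (cal/mol/K) derived as
# (dH - dG37)/310.15 K; hydrophilicity from the published dinucleotide
# scale.  All properties are standardized to zero mean / unit variance
# across the 16 dinucleotides before entering any encoder, so only the
# relative ordering and spacing of these values matters.
dinucleotide	shift	slide	rise	tilt	roll	twist	stacking_energy	enthalpy	entropy	free_energy	hydrophilicity
AA	-0.08	-1.27	3.18	-0.8	7.0	31.3	-5.9	-6.82	-18.99	-0.93	0.023
AC	0.23	-1.43	3.24	0.8	4.8	31.0	-9.3	-11.40	-29.54	-2.24	0.083
AG	-0.04	-1.50	3.30	0.5	8.5	30.5	-7.3	-10.48	-27.08	-2.08	0.035
AU	0.01	-1.36	3.24	1.1	7.1	33.2	-6.7	-9.38	-26.70	-1.10	0.090
CA	0.07	-1.46	3.09	1.0	9.9	32.8	-7.6	-10.44	-26.86	-2.11	0.118
CC	-0.01	-1.78	3.32	0.3	8.7	33.0	-9.1	-13.39	-32.66	-3.26	0.349
CG	0.30	-1.89	3.30	-0.1	12.1	29.8	-10.2	-10.64	-26.70	-2.36	0.193
CU	-0.04	-1.50	3.30	0.5	8.5	30.5	-7.3	-10.48	-27.08	-2.08	0.378
GA	-0.02	-1.70	3.38	1.3	9.4	32.6	-9.8	-12.44	-32.53	-2.35	0.048
GC	0.07	-1.39	3.22	0.0	6.1	35.0	-13.2	-14.88	-36.95	-3.42	0.146
GG	-0.01	-1.78	3.32	0.3	8.7	33.0	-9.1	-13.39	-32.66	-3.26	0.065
GU	0.23	-1.43	3.24	0.8	4.8	31.0	-9.3	-11.40	-29.54	-2.24	0.160
UA	-0.02	-1.45	3.26	-0.2	10.7	32.0	-5.3	-7.69	-20.51	-1.33	0.112
UC	-0.02	-1.70	3.38	1.3	9.4	32.6	-9.8	-12.44	-32.53	-2.35	0.132
UG	0.07	-1.46	3.09	1.0	9.9	32.8	-7.6	-10.44	-26.86	-2.11	0.054
UU	-0.08	-1.27	3.18	-0.8	7.0	31.3	-5.9	-6.82	-18.99	-0.93	0.100
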