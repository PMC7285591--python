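# DNA dinucleotide physicochemical property table (11 properties).
# Structural base-step parameters (shift/slide/rise in Angstrom,
# tilt/roll/twist in degrees) compiled from published B-DNA crystal-structure
# averages; stacking energies (kcal/mol) from published dimer-stacking
# calculations; enthalpy (kcal/mol), entropy (cal/mol/K) and free energy at
# 37C (kcal/mol) from the unified nearest-neighbor thermodynamic parameter
# set (SantaLucia 1998); hydrophilicity from the published dinucleotide
# scale.  All properties are standardized to zero mean / unit variance
# across the 16 dinucleotides before entering any encoder, so only the
# relative ordering and spacing of these values matters.
dinucleotide	shift	slide	rise	tilt	roll	twist	stacking_energy	enthalpy	entropy	free_energy	hydrophilicity
AA	-0.03	-0.08	3.27	-1.4	0.7	35.1	-5.37	-7.9	-22.2	-1.00	0.04
AC	0.13	-0.58	3.36	-0.5	0.7	31.5	-10.51	-8.4	-22.4	-1.44	0.14
AG	0.09	-0.25	3.34	-1.5	4.5	31.9	-6.78	-7.8	-21.0	-1.28	0.08
AT	0.00	-0.59	3.31	0.0	1.1	29.3	-6.57	-7.2	-20.4	-0.88	0.14
CA	0.09	0.53	3.33	0.5	4.7	37.3	-6.57	-8.5	-22.7	-1.45	0.21
CC	0.05	-0.22	3.42	-0.1	3.6	32.9	-8.26	-8.0	-19.9	-1.84	0.49
CG	0.00	0.41	3.39	0.0	5.4	36.1	-9.61	-10.6	-27.2	-2.17	0.35
CT	-0.09	-0.25	3.34	1.5	4.5	31.9	-6.78	-7.8	-21.0	-1.28	0.52
GA	-0.28	0.09	3.37	-0.7	1.9	36.3	-9.81	-8.2	-22.2	-1.30	0.10
GC	0.00	-0.38	3.40	0.0	0.3	33.6	-14.59	-9.8	-24.4	-2.24	0.26
GG	-0.05	-0.22	3.42	0.1	3.6	32.9	-8.26	-8.0	-19.9	-1.84	0.17
GT	-0.13	-0.58	3.36	0.5	0.7	31.5	-10.51	-8.4	-22.4	-1.44	0.27
TA	0.00	0.05	3.42	0.0	3.3	37.8	-3.82	-7.2	-21.3	-0.58	0.24
TC	0.28	0.09	3.37	0.7	1.9	36.3	-9.81	-8.2	-22.2	-1.30	0.27
TG	-0.09	0.53	3.33	-0.5	4.7	37.3	-6.57	-8.5	-22.7	-1.45	0.17
TT	0.03	-0.08	3.27	1.4	0.7	35.1	-5.37	-7.9	-22.2	-1.00	0.21
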