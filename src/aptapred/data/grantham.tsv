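# Grantham chemical distance matrix, recomputed from the published
# formula D = rho*sqrt(1.833*dc^2 + 0.1018*dp^2 + 0.000399*dv^2)
# with Grantham (1974) composition/polarity/volume values;
# rho scales the mean pairwise distance to 100.
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	195.261	125.914	106.853	112.73	60.074	85.606	93.786	105.71	96.314	84.551	110.564	26.91	90.881	111.411	99.263	58.1	64.515	147.921	111.735
C	195.261	0	153.777	169.661	204.658	158.44	174.072	197.51	201.845	197.689	195.812	138.949	168.813	154.434	179.772	111.82	149.126	191.485	214.645	193.98
D	125.914	153.777	0	44.663	176.759	93.891	81.345	168.303	101.591	171.984	160.238	23.036	108.052	61.365	95.94	65.557	85.188	152.214	190.804	160.148
E	106.853	169.661	44.663	0	140.397	97.981	40.848	134.339	56.943	138.525	126.251	40.913	93.854	29.312	54.09	79.893	65.588	121.488	152.46	122.939
F	112.73	204.658	176.759	140.397	0	153.327	100.127	21.305	102.276	21.853	28.565	158.321	113.877	115.739	97.161	155.012	102.994	50.001	39.707	21.638
G	60.074	158.44	93.891	97.981	153.327	0	97.662	135.597	126.625	137.873	127.112	79.45	41.684	87.281	125.294	55.34	59.234	108.931	184.033	147.12
H	85.606	174.072	81.345	40.848	100.127	97.662	0	94.462	32.446	98.823	86.458	68.445	76.378	24.116	28.857	89.053	46.815	84.004	114.712	83.438
I	93.786	197.51	168.303	134.339	21.305	135.597	94.462	0	101.746	4.862	10.134	149.11	95.502	108.709	97.715	141.985	89.401	29.648	60.608	33.091
K	105.71	201.845	101.591	56.943	102.276	126.625	32.446	101.746	0	106.476	94.615	94.006	102.849	53.299	26.038	120.692	77.844	97.125	109.579	84.898
L	96.314	197.689	171.984	138.525	21.853	137.873	98.823	4.862	106.476	0	14.322	152.532	97.905	112.59	102.015	144.269	92.476	31.827	61.061	35.724
M	84.551	195.812	160.238	126.251	28.565	127.112	86.458	10.134	94.615	14.322	0	141.339	86.709	101.032	91.759	135.042	81.147	21.55	66.725	35.269
N	110.564	138.949	23.036	40.913	158.321	79.45	68.445	149.11	94.006	152.532	141.339	0	90.276	45.813	85.226	46.301	64.86	133.053	174.011	142.417
P	26.91	168.813	108.052	93.854	113.877	41.684	76.378	95.502	102.849	97.905	86.709	90.276	0	75.235	102.85	73.449	37.613	67.876	146.814	109.76
Q	90.881	154.434	61.365	29.312	115.739	87.281	24.116	108.709	53.299	112.59	101.032	45.813	75.235	0	42.87	68.288	41.159	96.453	130.376	98.914
R	111.411	179.772	95.94	54.09	97.161	125.294	28.857	97.715	26.038	102.015	91.759	85.226	102.85	42.87	0	109.357	71.065	95.923	101.424	77.209
S	99.263	111.82	65.557	79.893	155.012	55.34	89.053	141.985	120.692	144.269	135.042	46.301	73.449	68.288	109.357	0	57.825	123.196	176.81	143.296
T	58.1	149.126	85.188	65.588	102.994	59.234	46.815	89.401	77.844	92.476	81.147	64.86	37.613	41.159	71.065	57.825	0	69.588	128.485	92.369
V	64.515	191.485	152.214	121.488	50.001	108.931	84.004	29.648	97.125	31.827	21.55	133.053	67.876	96.453	95.923	123.196	69.588	0	88.08	54.735
W	147.921	214.645	190.804	152.46	39.707	184.033	114.712	60.608	109.579	61.061	66.725	174.011	146.814	130.376	101.424	176.81	128.485	88.08	0	37.163
Y	111.735	193.98	160.148	122.939	21.638	147.12	83.438	33.091	84.898	35.724	35.269	142.417	109.76	98.914	77.209	143.296	92.369	54.735	37.163	0
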