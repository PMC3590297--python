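# element	covalent_A	vdw_A	mass_amu	color_r	color_g	color_b
# Covalent radii: Cordero et al. 2008 (C sp3, Fe low spin);
# van der Waals radii: Bondi 1964 (metals: Batsanov-style estimates).
# Colors: CPK-like display convention, 0-255.
H	0.31	1.20	1.008	255	255	255
C	0.76	1.70	12.011	80	80	80
N	0.71	1.55	14.007	48	80	248
O	0.66	1.52	15.999	255	13	13
P	1.07	1.80	30.974	255	128	0
S	1.05	1.80	32.06	255	255	48
F	0.57	1.47	18.998	144	224	80
CL	1.02	1.75	35.45	31	240	31
BR	1.20	1.85	79.904	166	41	41
I	1.39	1.98	126.904	148	0	148
NA	1.66	2.27	22.990	171	92	242
MG	1.41	1.73	24.305	138	255	0
K	2.03	2.75	39.098	143	64	212
CA	1.76	2.31	40.078	61	255	0
MN	1.39	2.05	54.938	156	122	199
FE	1.32	2.04	55.845	224	102	51
CO	1.26	2.00	58.933	240	144	160
NI	1.24	1.97	58.693	80	208	80
CU	1.32	1.96	63.546	200	128	51
ZN	1.22	2.01	65.38	125	128	176
SE	1.20	1.90	78.971	255	161	0
X	0.77	1.50	0.0	255	20	147
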