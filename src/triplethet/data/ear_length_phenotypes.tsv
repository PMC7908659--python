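line	parent1	parent2	young_ear_mm_mean	young_ear_mm_sd	young_lsd_letter	young_mph_pct	mature_ear_cm_mean	mature_ear_cm_sd	mature_lsd_letter	mature_mph_pct
T121			3.79	0.08	e		19.52	1.18	e
T126			2.58	0.06	g		13.52	0.83	g
PH4CV			2.42	0.08	g		11.26	1.08	h
PH6WC			3.26	0.05	f		17.03	1.03	f
T121xPH4CV	T121	PH4CV	5.37	0.15	b	72.95	25.53	1.48	b	65.89
T126xPH4CV	T126	PH4CV	4.53	0.06	d	81.20	20.06	1.35	e	61.90
T121xPH6WC	T121	PH6WC	5.89	0.17	a	67.09	27.01	1.56	a	47.80
T126xPH6WC	T126	PH6WC	5.11	0.11	bc	75.00	22.51	1.02	d	47.36
T121xT126	T121	T126	4.84	0.07	c	51.96	23.82	1.28	c	44.19
PH4CVxPH6WC	PH4CV	PH6WC	4.68	0.09	cd	64.79	22.78	1.19	d	61.05
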