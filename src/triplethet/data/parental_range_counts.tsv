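triplet	within_range	within_pct	out_of_range	out_pct
T121-T126-T121xT126	16371	64.97	8828	35.03
T121-PH4CV-T121xPH4CV	14509	57.58	10690	42.42
T121-PH6WC-T121xPH6WC	14980	59.45	10219	40.55
T126-PH4CV-T126xPH4CV	17027	67.57	8172	32.43
T126-PH6WC-T126xPH6WC	14874	59.03	10325	40.97
PH4CV-PH6WC-PH4CVxPH6WC	15420	61.19	9779	38.81
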