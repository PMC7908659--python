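sample_id	raw_reads	clean_reads	retention_rate_pct	mapped_reads	mapped_rate_pct
T121-1	13871140	13443019	96.91	11622834	86.46
T121-2	16291424	15500533	95.15	13091750	84.46
T126-1	17965773	17397315	96.84	14993006	86.18
T126-2	18368761	17927296	97.60	15485598	86.38
PH4CV-1	14658208	13170436	89.85	10408596	79.03
PH4CV-2	21755428	19974317	91.81	16185189	81.03
PH6WC-1	15884601	15718724	98.96	13711443	87.23
PH6WC-2	14723316	14399270	97.80	12569123	87.29
T121xPH4CV-1	14077347	13499094	95.89	11445882	84.79
T121xPH4CV-2	16779865	16290901	97.09	14021578	86.07
T121xPH6WC-1	18542048	18152498	97.90	15750923	86.77
T121xPH6WC-2	19966028	19316617	96.75	16480938	85.32
T121xT126-1	15417581	15241180	98.86	13401570	87.93
T121xT126-2	16935225	16415063	96.93	14049652	85.59
T126xPH4CV-1	15196264	14513192	95.51	12233170	84.29
T126xPH4CV-2	19608143	18982604	96.81	16230126	85.50
PH4CVxPH6WC-1	14888697	14495750	97.36	12502584	86.25
PH4CVxPH6WC-2	15276520	14917001	97.65	12855471	86.18
T126xPH6WC-1	17312865	16694768	96.43	14243976	85.32
T126xPH6WC-2	15023955	14778806	98.37	12903376	87.31
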