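region	sex	normal	possible_AD	probable_AD	definite_AD	overlap	score_printed
frontal pole	male	552223	86973	12790	432782	261	0.999527365
frontal pole	female	777879	433862	270613	167646	47810	0.938538
occipital visual cortex	male	527769	261508	NA	155842	17399	0.967032925
occipital visual cortex	female	351564	543264	233300	254039	43249	0.876981
inferior temporal gyrus	male	198612	106157	NA	433929	10671	0.946272129
inferior temporal gyrus	female	316910	375176	273127	307081	45335	0.856947
middle temporal gyrus	male	430642	93704	NA	235468	14030	0.967420735
middle temporal gyrus	female	688423	422968	298747	370383	49419	0.8837
superior temporal gyrus	male	355013	11511	NA	296203	687	0.99806486
superior temporal gyrus	female	688423	339404	624409	112770	52336	0.923977
posterior cingulate cortex	male	358495	176717	NA	562718	31813	0.911259571
posterior cingulate cortex	female	894835	250078	563781	177025	45752	0.948871
anterior cingulate	male	611561	48430	10426	930858	136	0.999777618
anterior cingulate	female	311564	677160	326324	383965	73530	0.763997
parahippocampal gyrus	male	617064	5231	NA	507297	671	0.998912593
parahippocampal gyrus	female	361783	422968	402422	149879	40953	0.886802
temporal pole	male	565399	41958	8334	548532	87	0.999846126
temporal pole	female	680216	308743	391154	282634	69685	0.897555
precentral gyrus	male	14236	116408	NA	663736	585	0.958906996
precentral gyrus	female	361783	588083	383589	358904	12468	0.851795
inferior frontal gyrus	male	240356	205034	6214	563532	85	0.999646358
inferior frontal gyrus	female	1260395	399279	817409	325913	111796	0.911301
dorsolateral prefrontal cortex	male	888593	371582	NA	153308	32605	0.963307161
dorsolateral prefrontal cortex	female	478807	611679	419392	290019	73000	0.847538
superior parietal lobule	male	614800	287773	NA	65717	9949	0.983817502
superior parietal lobule	female	577592	666463	482516	269236	74781	0.87053
prefrontal cortex	male	416658	40038	6977	543842	40	0.999903998
prefrontal cortex	female	775398	999755	554521	293055	113178	0.854039
caudate nucleus	male	237057	45562	NA	528826	4177	0.982379765
caudate nucleus	female	599185	411294	436888	500654	92857	0.845028
hippocampus	male	335324	29830	NA	599797	6002	0.982100893
hippocampus	female	289056	270554	320649	220469	27797	0.903835
putamen	male	61558	48685	NA	515028	1383	0.977533383
putamen	female	574247	400815	300052	279224	59840	0.829789
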