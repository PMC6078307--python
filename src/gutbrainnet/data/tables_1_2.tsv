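table	block_a	block_b	variable_a	variable_b	modality	r	p	p_display	q	q_display	df
1	metabolite	brain	Indole	B_R_NAcc	functional	0.59608	0.0009	< 0.001	0.0009	< 0.001	62
1	metabolite	brain	IAA	S_R_Amg	functional	0.37640	0.003	0.003	0.011	0.011	62
1	metabolite	brain	Indole	S_R_NAcc	functional	0.36637	0.004	0.004	0.011	0.011	62
1	metabolite	brain	IAA	S_R_NAcc	functional	0.33201	0.009	0.009	0.018	0.018	62
1	metabolite	brain	Skatole	S_R_NAcc	functional	0.31022	0.015	0.015	0.022	0.022	62
1	metabolite	brain	Skatole	S_L_NAcc	functional	0.33839	0.008	0.008	0.046	0.046	62
1	clinical	brain	YFAS	S_L_NAcc	functional	0.59632	0.0009	< 0.001	0.0009	< 0.001	41
1	clinical	brain	ANX	S_L_NAcc	functional	0.29999	0.019	0.019	0.056	0.056	62
1	clinical	brain	YFAS	S_R_NAcc	functional	0.36944	0.019	0.019	0.114	0.114	62
1	metabolite	brain	Skatole	S_L_Amg	anatomical	0.55362	0.0009	< 0.001	0.0009	< 0.001	61
1	metabolite	clinical	Skatole	YFAS		0.48043	0.002	0.002	0.017	0.017	41
1	metabolite	clinical	Indole	ANX		-0.28741	0.025	0.025	0.086	0.086	62
1	metabolite	clinical	Indole	BMI		0.28036	0.029	0.029	0.090	0.090	62
2	metabolite	brain	IAA	S_R_Amg	functional	0.37639	0.003	0.003	0.042	0.042	62
2	metabolite	brain	Skatole	B_L_ALSVerp	functional	0.33542	0.008	0.008	0.123	0.123	62
2	metabolite	brain	IAA	S_R_ALSVerp	functional	0.27091	0.035	0.035	0.206	0.206	62
2	metabolite	brain	IAA	S_L_ALSHorp	functional	0.26168	0.042	0.042	0.625	0.625	62
2	clinical	brain	YFAS	B_L_ALSVerp	functional	0.53843	0.0009	< 0.001	0.005	0.005	41
2	clinical	brain	BMI	B_R_ShoInG	functional	0.29197	0.022	0.022	0.336	0.336	62
2	metabolite	brain	Skatole	S_L_Amg	anatomical	0.55362	0.0009	< 0.001	0.0009	< 0.001	61
2	metabolite	brain	Indole	B_L_ALSHorp	anatomical	0.49712	0.0009	< 0.001	0.0009	< 0.001	61
2	metabolite	brain	Skatole	S_R_ALSHorp	anatomical	0.31036	0.016	0.016	0.237	0.237	61
2	metabolite	brain	Skatole	S_R_ALSVerp	anatomical	0.26351	0.042	0.042	0.314	0.314	61
2	metabolite	brain	Skatole	B_R_ALSHorp	anatomical	0.25465	0.0499	< 0.050	0.503	0.503	61
2	clinical	brain	BMI	B_L_ShoInG	anatomical	0.30157	0.019	0.019	0.288	0.288	61
2	metabolite	clinical	Skatole	YFAS		0.48043	0.002	0.002	0.017	0.017	41
2	metabolite	clinical	Indole	ANX		-0.28741	0.025	0.025	0.086	0.086	62
2	metabolite	clinical	Indole	BMI		0.28036	0.029	0.029	0.090	0.090	62
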