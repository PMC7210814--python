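hsa-miR-148a	MARCO	TCIM
hsa-miR-302d	CAP2	ECM1	HAMP	TCIM
has-miR-1	CAP2	TCIM
hsa-miR-133a	TCIM
hsa-miR-130a	CAP2	FCN3	UBD	OIT3	CLEC1B	TCIM	CLEC4G
hsa-miR-93	DCN	CAP2	TCIM
hsa-miR-106b	DCN	CAP2	TCIM
hsa-miR-133b	TCIM
hsa-miR-96	CAP2	ECM1	HAMP	TCIM
hsa-miR-144	CAP2	ECM1	HAMP	TCIM
hsa-miR-183	CAP2	ECM1	HAMP	TCIM
hsa-miR-182	CAP2	ECM1	HAMP	TCIM
hsa-miR-135a	CAP2	TCIM
hsa-miR-138	CAP2	TCIM
hsa-miR-542-3p	CAP2	ECM1	HAMP	TCIM
hsa-miR-497	VIPR1	CAP2	ECM1	MARCO	HAMP	TCIM
hsa-miR-195	VIPR1	CAP2	ECM1	MARCO	HAMP	TCIM
hsa-miR-222	DBH	CAP2	RND3	ECM1	HAO2	CNDP1	CETP	OIT3	CLEC1B	SRD5A2	HAMP	TCIM
has-miR-221	DBH	CAP2	RND3	ECM1	HAO2	CNDP1	CETP	OIT3	CLEC1B	SRD5A2	HAMP	TCIM
hsa-miR-10a	CAP2	TCIM
hsa-miR-203	TCIM
hsa-miR-100	MARCO	TCIM
hsa-miR-126	CAP2	ECM1	HAMP	TCIM
hsa-miR-99a	CAP2	ECM1	HAMP	TCIM
hsa-miR-505	CAP2	ECM1	HAMP	TCIM
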