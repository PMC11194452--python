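sample_id	doc_umol_L	fdom_protein_like	fdom_humic_like
control_irradiated_r1	81.36	41.75	71.98
control_irradiated_r2	81.36	41.75	71.98
control_irradiated_r3	81.36	41.75	71.98
control_non_irradiated_r1	73.62	45.21	110.56
control_non_irradiated_r2	73.62	45.21	110.56
control_non_irradiated_r3	73.62	45.21	110.56
LDPE_irradiated_r1	94.5	51.67	64.57
LDPE_irradiated_r2	94.5	51.67	64.57
LDPE_irradiated_r3	94.5	51.67	64.57
LDPE_non_irradiated_r1	79.56	50.54	117.71
LDPE_non_irradiated_r2	79.56	50.54	117.71
LDPE_non_irradiated_r3	79.56	50.54	117.71
aged_irradiated_r1	665.87	972.84	309.66
aged_irradiated_r2	665.87	972.84	309.66
aged_irradiated_r3	665.87	972.84	309.66
aged_non_irradiated_r1	492.53	1695.0	573.92
aged_non_irradiated_r2	492.53	1695.0	573.92
aged_non_irradiated_r3	492.53	1695.0	573.92
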