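sample_id	plastic	light	replicate	timepoint
control_irradiated_r1	control	irradiated	1	t4
control_irradiated_r2	control	irradiated	2	t4
control_irradiated_r3	control	irradiated	3	t4
control_non_irradiated_r1	control	non_irradiated	1	t4
control_non_irradiated_r2	control	non_irradiated	2	t4
control_non_irradiated_r3	control	non_irradiated	3	t4
LDPE_irradiated_r1	LDPE	irradiated	1	t4
LDPE_irradiated_r2	LDPE	irradiated	2	t4
LDPE_irradiated_r3	LDPE	irradiated	3	t4
LDPE_non_irradiated_r1	LDPE	non_irradiated	1	t4
LDPE_non_irradiated_r2	LDPE	non_irradiated	2	t4
LDPE_non_irradiated_r3	LDPE	non_irradiated	3	t4
aged_irradiated_r1	aged	irradiated	1	t4
aged_irradiated_r2	aged	irradiated	2	t4
aged_irradiated_r3	aged	irradiated	3	t4
aged_non_irradiated_r1	aged	non_irradiated	1	t4
aged_non_irradiated_r2	aged	non_irradiated	2	t4
aged_non_irradiated_r3	aged	non_irradiated	3	t4
inoculum	inoculum	none	1	t0
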