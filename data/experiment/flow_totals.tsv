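sample_id	cells_per_mL
control_irradiated_r1	2865445.5193603276
control_irradiated_r2	3017111.0154606556
control_irradiated_r3	3455023.331610665
control_non_irradiated_r1	2818182.5724923764
control_non_irradiated_r2	2967725.03727247
control_non_irradiated_r3	2256030.251661726
LDPE_irradiated_r1	3042170.1251497744
LDPE_irradiated_r2	3394959.248088259
LDPE_irradiated_r3	3237308.6720728655
LDPE_non_irradiated_r1	2494608.760571394
LDPE_non_irradiated_r2	2696693.513431793
LDPE_non_irradiated_r3	2977993.2390022147
aged_irradiated_r1	14180495.029826595
aged_irradiated_r2	14558579.667993568
aged_irradiated_r3	8196219.547061801
aged_non_irradiated_r1	10452387.37172366
aged_non_irradiated_r2	10482309.12507525
aged_non_irradiated_r3	9780151.023520406
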