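mu_name,group_density_per_km2,individual_density_per_km2,group_size,forest_area_ha,population_size,ci_low,ci_high,management_type
Aldeia Velha,2.41,7.1,5.06,6993,499,248,749,reintroduced
PDA-Cambucaes,2.26,16.2,7.18,4503,731,570,892,wild
Uniao-Faz Dourada,1.35,6.1,4.48,4112,249,102,396,translocated
Pirineus,1.88,9.7,5.16,13444,1303,821,1783,wild
Rio Vermelho,2.49,19.0,7.64,996,189,154,225,reintroduced
Imbau,2.34,19.0,8.12,3120,593,482,705,reintroduced
Gavioes-Lavras,0.37,1.7,4.67,8243,142,36,437,wild
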