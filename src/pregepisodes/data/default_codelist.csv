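pattern,system,category,ga_min_days,ga_max_days,valid_from,valid_to
DELV,procedure,delivery_procedure,,,,
DELC,procedure,delivery_procedure,,,,
O364,diagnosis,stillbirth_diagnosis,,,,
Z371,diagnosis,stillbirth_diagnosis,,,,
O03,diagnosis,abortion_diagnosis,,,,
O04,diagnosis,abortion_diagnosis,,,,
O05,diagnosis,abortion_diagnosis,,,,
O06,diagnosis,abortion_diagnosis,,,,
O04,diagnosis,induced_abortion_marker,,,,
ABIN,procedure,induced_abortion_marker,,,,
US101,procedure,sonography_t1,0,97,2013-01-01,
US102,procedure,sonography_t1_targetscan,70,97,2013-01-01,
US201,procedure,sonography_t23,98,293,2013-01-01,
US202,procedure,sonography_t23_targetscan,112,224,2013-01-01,
O60,diagnosis,preterm_ga_unspecified,,,,
O601,diagnosis,preterm_ga_specified,140,195,2016-01-01,
O602,diagnosis,preterm_ga_specified,196,237,2016-01-01,
O603,diagnosis,preterm_ga_specified,238,258,2016-01-01,
ABPR,procedure,abortion_procedure,21,97,,
L01AA01,drug,drug_cyc_mmf_mtx,,,,
L04AA06,drug,drug_cyc_mmf_mtx,,,,
L01BA01,drug,drug_cyc_mmf_mtx,,,,
M01A,drug,drug_nsaid,,,,
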