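project_id,n_tested,sd_hit_rate,dr_hit_rate,potency_range_um,n_analogs,analog_sd_rate,analog_dr_rate,analog_potency_range_um,n_training_actives,structure_source,target_class,assay_type
ASAH1,376,10.64,7.71,0.3-102,,,,,,,,
AXL,597,12.06,8.21,0.181-71,3200,35.59,33.56,0.079-86,,,kinase,
BCL2,422,3.08,0.00,,,,,,,,,
CBLB,422,1.66,0.00,,,,,,,,,
CDK5,786,10.69,10.43,0.049-79,587,47.53,43.61,0.43-76,,,kinase,
CDK7,786,10.69,10.56,0.099-60,735,28.44,27.35,0.191-10,,cryoem,kinase,
GFPT1,384,6.51,2.34,31-86,734,24.93,24.11,1-194,,,,
KCNT1,416,9.62,7.69,1.1-30,,,,,,,ion_channel,
KDM6A,356,3.93,1.12,24-58,,,,,,,,
LATS1,418,18.18,17.94,0.077-82,841,51.72,45.78,0.034-98,0,homology,kinase,
MC2R,208,11.54,9.62,16-68,419,39.38,38.42,2.4-97,,,gpcr,
MDM4,422,2.37,0.47,5.9-29.8,192,18.23,18.23,4.4-90,,,ppi,
NT5E,335,1.49,0.30,176,221,9.95,1.8,18.3-65,,,,
PARG,334,7.78,7.78,15-250,,,,,,,,
PARP14,576,5.38,2.95,3-96,616,26.46,26.30,0.2-95,,,,
POLQ,330,11.82,11.52,1.2-49,559,11.27,8.77,1.5-42,,,,
PPARA,422,4.03,0.24,131,211,14.22,3.79,59-95,,,nuclear_receptor,
PPM1D,530,11.89,6.98,4.5-98,,,,,,,,
PRMT5,422,4.03,0.95,7.2-79,415,7.95,5.54,19-114,,,,
PRODH,2542,2.77,1.11,15-84,,,,,,,,
TYK2,189,38.10,34.39,0.016-9,457,71.33,60.39,0.006-10,,,kinase,
VCP,416,4.81,4.81,2.4-64,738,,,,,,,
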