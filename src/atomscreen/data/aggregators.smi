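# Reference list of known colloidal aggregators (synthetic desk-scale list of
# literature-reported aggregator chemotypes) used for optional similarity-based
# aggregator removal (similarity >= 0.85 flags a candidate).
Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2	agg_catechin
O=C(c1ccccc1)c1cc(O)c(O)c(O)c1	agg_trihydroxybenzophenone
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	agg_resveratrol
O=C1c2cc(O)ccc2O/C1=C\c1ccc(O)cc1	agg_aurone
Oc1ccc(C2Sc3cc(O)ccc3O2)cc1	agg_benzoxathiole
O=C(O)c1ccccc1-c1ccc2cc(O)ccc2c1	agg_naphthylbenzoate
Clc1ccc(-c2nc3ccccc3s2)cc1	agg_chlorophenylbenzothiazole
O=C(Nc1ccc2ccccc2c1)c1cccc2ccccc12	agg_naphthamide
Oc1ccc(-c2cc(-c3ccc(O)cc3)cc(-c3ccc(O)cc3)c2)cc1	agg_trisphenol
O=C(c1ccc2ccccc2c1)c1ccc2ccccc2c1	agg_dinaphthylketone
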