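# Default screening-library filter rules: drug-likeness property ranges plus
# structural alerts (reactive/interfering substructures and a PAINS-A subset).
# This is a documented representative rule set in the spirit of published
# medicinal-chemistry filter collections, editable per campaign.
provenance: atomscreen default rule set v1
property_ranges:
  - [mw, 150, 550]
  - [clogp, -4.0, 5.5]
  - [hbd, 0, 5]
  - [hba, 0, 10]
  - [rotatable_bonds, 0, 10]
  - [tpsa, 0, 150]
alert_patterns:
  # reactive / covalent warheads
  - [acyl_halide, "[CX3](=O)[F,Cl,Br,I]"]
  - [sulfonyl_halide, "S(=O)(=O)[F,Cl,Br,I]"]
  - [alkyl_halide_activated, "[CH2][Br,I]"]
  - [aldehyde, "[CX3H1](=O)[#6]"]
  - [michael_acceptor_nitrile, "C=C-C#N"]
  - [epoxide, "C1OC1"]
  - [aziridine, "C1NC1"]
  - [isocyanate, "N=C=O"]
  - [isothiocyanate, "N=C=S"]
  - [anhydride, "C(=O)OC(=O)"]
  - [peroxide, "[OX2][OX2]"]
  - [azide, "[N-]=[N+]=N"]
  - [diazo, "[N+]#N"]
  - [hydrazine, "[NX3][NX3H2]"]
  - [acyl_hydrazide, "C(=O)N[NH2]"]
  - [thiol, "[SX2H]"]
  - [phosphorus_halide, "P[F,Cl,Br,I]"]
  - [beta_lactam, "O=C1CCN1"]
  # assay interference / instability
  - [nitro, "[N+](=O)[O-]"]
  - [nitroso, "[NX2]=O"]
  - [n_oxide, "[#7+][O-]"]
  - [quinone, "O=C1C=CC(=O)C=C1"]
  - [polyene_chain, "C=CC=CC=CC=C"]
  - [disulfide, "[SX2][SX2]"]
  - [thiourea, "NC(=S)N"]
  - [imine_of_aniline, "c[NX2]=[CX3]"]
  - [crown_like_polyether, "OCCOCCOCCO"]
  # PAINS-A style frequent hitters
  - [pains_rhodanine, "O=C1CSC(=S)N1"]
  - [pains_ene_rhodanine, "S1C(=S)N(C(=O)C1)"]
  - [pains_catechol, "c1cc(O)c(O)cc1"]
  - [pains_hydroxyphenyl_hydrazone, "Oc1ccccc1C=N[NX3]"]
  - [pains_alkylidene_barbiturate, "O=C1NC(=O)NC(=O)C1=C"]
  - [pains_azo, "cN=Nc"]
  - [pains_mannich_phenol, "Oc1ccccc1CN(C)C"]
  - [pains_aminothiophene_ester, "c1cc(N)sc1C(=O)O"]
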