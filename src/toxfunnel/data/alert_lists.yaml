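# Demonstrative structural-alert (toxicophore) lists, one block per
# toxicity category. These are classic literature toxicophores meant to
# exercise and demonstrate the screen; they are NOT a reproduction of any
# proprietary alert database, and funnel counts obtained with them are
# illustrative only. Swap in your own lists or an exported verdict table
# for production screening.
mutagenicity:
  - {name: nitroaromatic, smarts: "c[N+](=O)[O-]", level: high}
  - {name: aromatic_nitroso, smarts: "c[NX2]=O", level: high}
  - {name: azo, smarts: "[#6]N=N[#6]", level: high}
  - {name: epoxide, smarts: "C1OC1", level: high}
  - {name: aziridine, smarts: "C1CN1", level: high}
  - {name: nitrosamine, smarts: "[NX3][NX2]=O", level: high}
  - {name: primary_aromatic_amine, smarts: "[NX3H2]c", level: low}
tumorigenicity:
  - {name: hydrazine, smarts: "[NX3][NX3]", level: high}
  - {name: alkyl_halide_primary, smarts: "[CH2X4][Cl,Br,I]", level: low}
  - {name: azide, smarts: "N=[N+]=[N-]", level: high}
  - {name: michael_acceptor_enone, smarts: "C=C[CX3]=O", level: low}
  - {name: polyhalogenated_methyl, smarts: "C(Cl)(Cl)Cl", level: low}
reproductive:
  - {name: phthalate_diester, smarts: "c1ccc(C(=O)O[#6])c(C(=O)O[#6])c1", level: high}
  - {name: sulfonate_ester, smarts: "[#6]OS(=O)(=O)[#6]", level: high}
  - {name: glycol_ether, smarts: "[CH3][CH2]O[CH2][CH2]O", level: low}
hepatotoxicity:
  - {name: nitroaromatic, smarts: "c[N+](=O)[O-]", level: high}
  - {name: thiophene_ring, smarts: "c1ccsc1", level: low}
  - {name: acetanilide, smarts: "O=C([#6])Nc1ccccc1", level: low}
  - {name: hydrazide, smarts: "C(=O)[NX3][NX3]", level: high}
immunotoxicity:
  - {name: isocyanate, smarts: "[NX2]=C=O", level: high}
  - {name: maleimide, smarts: "O=C1C=CC(=O)N1", level: high}
  - {name: aliphatic_aldehyde, smarts: "[CX3H1](=O)[CX4]", level: low}
  - {name: acyl_halide, smarts: "[CX3](=O)[Cl,Br]", level: high}
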