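# Default focal-epilepsy gene panel: 21 genes screened by the customized
# multiplex-PCR panel, with the transcript used for annotation, whether loss of
# function is an established disease mechanism for the gene (licenses the
# null-variant pathogenicity rule), the gene's phenotype spectrum as controlled
# tags (used for genotype-phenotype matching), and the inheritance mode.
# Spectra are literature-derived defaults and are meant to be edited per site.
genes:
  - symbol: SCN1A
    transcript: NM_001165963.1
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [DRAVET, GEFS_PLUS, FEBRILE_SEIZURES, FOCAL_EPILEPSY]
  - symbol: SCN1B
    transcript: NM_001037.5
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [GEFS_PLUS, FEBRILE_SEIZURES, TLE]
  - symbol: SCN2A
    transcript: NM_021007.3
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [BFIE, EPILEPTIC_ENCEPHALOPATHY]
  - symbol: SCN9A
    transcript: NM_002977.3
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [GEFS_PLUS, FEBRILE_SEIZURES]
  - symbol: DEPDC5
    transcript: NM_001242896.1
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [FOCAL_EPILEPSY, FLE, TLE, NFLE]
  - symbol: GRIN2A
    transcript: NM_000833.5
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [EAS, BECTS, FOCAL_EPILEPSY]
  - symbol: GRIN2B
    transcript: NM_000834.5
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [EPILEPTIC_ENCEPHALOPATHY, FOCAL_EPILEPSY]
  - symbol: PRRT2
    transcript: NM_145239.2
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [BFIE, PKD, FOCAL_EPILEPSY]
  - symbol: SLC2A1
    transcript: NM_006516
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [GLUT1_DS, EAS, FOCAL_EPILEPSY]
  - symbol: PCDH19
    transcript: NM_001184880.1
    lof_mechanism: true
    inheritance: x_linked_female_restricted
    phenotypes: [EFMR, EPILEPTIC_ENCEPHALOPATHY]
  - symbol: KCNT1
    transcript: NM_020822.2
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [NFLE, EPILEPTIC_ENCEPHALOPATHY]
  - symbol: KCNQ2
    transcript: NM_172107.4
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [BFNE, EPILEPTIC_ENCEPHALOPATHY]
  - symbol: KCNQ3
    transcript: NM_004519.3
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [BFNE]
  - symbol: KCNA2
    transcript: NM_004974.4
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [EPILEPTIC_ENCEPHALOPATHY]
  - symbol: CHRNA4
    transcript: NM_000744.6
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [NFLE, FLE]
  - symbol: CHRNB2
    transcript: NM_000748.2
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [NFLE, FLE]
  - symbol: CHRNA2
    transcript: NM_000742.3
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [NFLE, FLE]
  - symbol: LGI1
    transcript: NM_005097.3
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [TLE, FOCAL_EPILEPSY]
  - symbol: GABRG2
    transcript: NM_000816.3
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [GEFS_PLUS, FEBRILE_SEIZURES, DRAVET]
  - symbol: HCN1
    transcript: NM_021072.3
    lof_mechanism: false
    inheritance: autosomal_dominant
    phenotypes: [GEFS_PLUS, EPILEPTIC_ENCEPHALOPATHY]
  - symbol: CHD2
    transcript: NM_001271.3
    lof_mechanism: true
    inheritance: autosomal_dominant
    phenotypes: [EPILEPTIC_ENCEPHALOPATHY, LGS]
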