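name: hnscc-10-gene
carcinogens:
- alcohol
- smoking
mutation_threshold: 0.1
min_positive_genes: 4
increment_magnitude: 1.0e-06
age_weight: 1.0e-07
genes:
- name: TP53
  type: tumor_suppressor
  carcinogen_signs:
    alcohol: 1
    smoking: -1
  phenotype_effects:
  - action: proliferation
    direction: up
  - action: apoptosis
    direction: down
  - action: quiescence
    direction: down
  activates:
  - gene: TP73
    direction: up
  - gene: RB
    direction: up
  - gene: TP21
    direction: up
  - gene: TP16
    direction: up
  - gene: EGFR
    direction: up
  - gene: CCDN1
    direction: up
  - gene: MYC
    direction: up
  - gene: PIK3CA
    direction: up
  - gene: RAS
    direction: up
- name: TP73
  type: tumor_suppressor
  carcinogen_signs:
    alcohol: 0
    smoking: 0
  phenotype_effects:
  - action: apoptosis
    direction: down
  activates: []
- name: RB
  type: tumor_suppressor
  carcinogen_signs:
    alcohol: 0
    smoking: -1
  phenotype_effects:
  - action: proliferation
    direction: up
  - action: differentiation
    direction: up
  - action: quiescence
    direction: down
  activates:
  - gene: TP53
    direction: up
  - gene: CCDN1
    direction: up
- name: TP21
  type: tumor_suppressor
  carcinogen_signs:
    alcohol: 1
    smoking: -1
  phenotype_effects:
  - action: proliferation
    direction: up
  activates: []
- name: TP16
  type: tumor_suppressor
  carcinogen_signs:
    alcohol: 1
    smoking: 0
  phenotype_effects:
  - action: proliferation
    direction: up
  activates: []
- name: EGFR
  type: oncogene
  carcinogen_signs:
    alcohol: 1
    smoking: 1
  phenotype_effects:
  - action: proliferation
    direction: up
  activates: []
- name: CCDN1
  type: oncogene
  carcinogen_signs:
    alcohol: 1
    smoking: 1
  phenotype_effects:
  - action: apoptosis
    direction: down
  activates:
  - gene: TP21
    direction: up
- name: MYC
  type: oncogene
  carcinogen_signs:
    alcohol: 0
    smoking: 1
  phenotype_effects:
  - action: proliferation
    direction: up
  - action: differentiation
    direction: up
  - action: apoptosis
    direction: down
  activates:
  - gene: TP21
    direction: down
  - gene: RAS
    direction: up
- name: PIK3CA
  type: oncogene
  carcinogen_signs:
    alcohol: 0
    smoking: 1
  phenotype_effects:
  - action: apoptosis
    direction: down
  activates: []
- name: RAS
  type: oncogene
  carcinogen_signs:
    alcohol: 1
    smoking: 1
  phenotype_effects:
  - action: proliferation
    direction: up
  - action: differentiation
    direction: up
  - action: apoptosis
    direction: down
  activates:
  - gene: CCDN1
    direction: up
  - gene: MYC
    direction: up
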