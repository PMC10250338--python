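# Demo species model: 13 minicircles in 3 constant groups.
# Eleven gene circles share constant template CR1; atp6 and rnl each carry
# their own constant region.  Repeat regions A/B are tandem, C is dispersed.
species_id: demo13
seed: 20
gc_constant: 0.62

constant_templates:
  - id: CR1
    length: 900
    repeat_regions:
      - {id: A, unit_length: 30, min_units: 1, max_units: 4, tandem: true}
      - {id: B, unit_length: 20, min_units: 1, max_units: 3, tandem: true}
      - {id: C, unit_length: 25, min_units: 1, max_units: 3, tandem: false, spacer_length: 15}
  - id: CR2
    length: 750
    repeat_regions:
      - {id: D, unit_length: 24, min_units: 1, max_units: 3, tandem: true}
  - id: CR3
    length: 800
    repeat_regions:
      - {id: E, unit_length: 28, min_units: 1, max_units: 4, tandem: true}

genes:
  - {name: cob,   cds_length: 1140, ncr_length: 160, gc: 0.60}
  - {name: cox1,  cds_length: 1440, ncr_length: 150, gc: 0.61}
  - {name: cox2,  cds_length: 720,  ncr_length: 140, gc: 0.60}
  - {name: cox3,  cds_length: 780,  ncr_length: 150, gc: 0.62}
  - {name: nad1,  cds_length: 900,  ncr_length: 150, gc: 0.60}
  - {name: nad2,  cds_length: 1200, ncr_length: 140, gc: 0.59}
  - {name: nad3,  cds_length: 360,  ncr_length: 150, gc: 0.60}
  - {name: nad4,  cds_length: 1230, ncr_length: 160, gc: 0.61}
  - {name: nad5f, cds_length: 990,  ncr_length: 150, gc: 0.60}
  - {name: nad5s, cds_length: 810,  ncr_length: 140, gc: 0.61}
  - {name: atp9_rns, cds_length: 660, ncr_length: 150, gc: 0.62}
  - {name: atp6,  cds_length: 690,  ncr_length: 150, gc: 0.60}
  - {name: rnl,   cds_length: 1350, ncr_length: 160, gc: 0.58}

circle_plan:
  - {gene: cob,      template: CR1}
  - {gene: cox1,     template: CR1, units: {A: 2, B: 1, C: 3}}
  - {gene: cox2,     template: CR1, units: {A: 1, B: 2, C: 3}}
  - {gene: cox3,     template: CR1}
  - {gene: nad1,     template: CR1}
  - {gene: nad2,     template: CR1}
  - {gene: nad3,     template: CR1}
  - {gene: nad4,     template: CR1}
  - {gene: nad5f,    template: CR1}
  - {gene: nad5s,    template: CR1, units: {A: 1, B: 1, C: 1}}
  - {gene: atp9_rns, template: CR1}
  - {gene: atp6,     template: CR2}
  - {gene: rnl,      template: CR3}
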