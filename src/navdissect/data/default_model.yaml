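morphology:
  axial_resistivity: 150.0
  sections:
  - name: distal_dendrite
    length_um: 500.0
    diameter_um: 4.0
    n_segments: 10
    cm_uf_cm2: 1.0
  - name: proximal_dendrite
    length_um: 20.0
    diameter_um: 4.0
    n_segments: 2
    cm_uf_cm2: 1.0
  - name: soma
    length_um: 30.0
    diameter_um: 30.0
    n_segments: 3
    cm_uf_cm2: 1.0
  - name: AIS
    length_um: 50.0
    diameter_um: 1.5
    n_segments: 20
    cm_uf_cm2: 1.0
  - name: distal_axon
    length_um: 500.0
    diameter_um: 1.0
    n_segments: 10
    cm_uf_cm2: 0.02
  - name: node
    length_um: 1.5
    diameter_um: 1.0
    n_segments: 1
    cm_uf_cm2: 1.0
channels:
  reversal_mv:
    na: 60.0
    k: -90.0
    leak: -82.0
  ais_nav_total_ms_cm2: 900.0
  node_enrichment: 3.0
  densities_ms_cm2:
    soma:
      nav: 25.0
      kvf: 30.0
      leak: 0.025
    proximal_dendrite:
      nav: 25.0
      kvf: 20.0
      leak: 0.025
    distal_dendrite:
      nav: 25.0
      kvs: 5.0
      leak: 0.025
    AIS:
      kvf: 150.0
      leak: 0.5
    distal_axon:
      nav: 60.0
      kvf: 20.0
      leak: 0.02
    node:
      kvf: 150.0
      leak: 0.025
distribution:
  crossover_um: 15.0
  scale_nav12: 1.0
  scale_nav16: 1.0
drug:
  conc_nM: 0.0
  genotype:
    nav12: YW
    nav16: YW
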