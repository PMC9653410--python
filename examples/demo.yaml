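# End-to-end synthetic demonstration: generate a small undulating bilayer
# with one C2 dimer footprint (POPI/CHOL enrichment planted), then run every
# analysis stage.  Finishes in well under a minute on one CPU.
seed: 1
temperature: 310.0
output_dir: demo_out

generate:
  enabled: true
  box_x: 160.0
  box_y: 160.0
  lipids_per_leaflet: 400
  bending_modulus: 20.0       # kBT
  surface_tension: 0.0
  n_frames: 120
  deformations:
    - center: [80.0, 80.0]
      orientation: 45.0
      footprint_radius: 15.0
      amplitude: 4.0
      radial_center: 18.0
      radial_width: 8.0
      decay_length: 25.0
      dimer_id: D1
      enrichment: {POPI: 2.2, CHOL: 1.4}
  enrichment_cutoff: 7.0

heights:
  enabled: true
  bin_size: 2.0
  ring_width: 5.0

lipids:
  enabled: true
  cutoff: 7.0
  heatmap_types: [POPI, CHOL]

modulus:
  enabled: true
  grid_bin: 8.0
  exclusion_radius: 7.0

orient:
  enabled: true

landscape:
  enabled: true
  source: potential
  wells: [[45, 45], [135, 135]]
  depth: 4.0
  width: 40.0
  n_steps: 60000
  bin_width: 15.0
  depth_threshold: 1.0
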