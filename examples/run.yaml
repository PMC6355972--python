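# Demo pipeline: generate phantoms, measure them, report statistics.
seed: 7
out: runs/demo
stages:
  - name: simulate
    kinds: [sphere, protrusion, population]
    radius_um: 5.0
    n_cells_per_condition: 100
  - name: morphometry
    pattern: "*.ome.tif"
  - name: report
    model: saturating
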