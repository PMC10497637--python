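# End-to-end demo configuration: `coralcarb run --config examples/demo_config.yaml`
out_dir: pipeline_demo_out
seed: 2024
simulate: true
phantoms_per_status: 3
survey_transects_per_reef: 10
track_width_px: 5
smooth_window_cm: 0.05
min_prominence: 0.05
porosity_reference: step_at_slab
connectivity: 8
min_pore_area_px: 1
include_interaction: true
include_extension: true
contrast_adjustment: tukey
transect_area_m2: 10.0
branching_correction: 0.11
log_level: INFO
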