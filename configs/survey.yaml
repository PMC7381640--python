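# Study-condition synthetic survey run.  Every constant of the analysis is
# inspectable here; identical config + seed reproduce all outputs exactly.
outdir: results/survey_run
seed: 20
n_sites: 462
n_track_records: 1000
nai_live_time_s: 600.0      # 10-min fixed-point spectra
paired_live_time_s: 30.0    # 30-s paired shielding measurements
hpge_live_time_s: 30000.0
soil_mass_kg: 0.13
dcf: 0.14                   # nGy/h per cps
cosmic_cps_per_channel: 0.01
grid_spacing_deg: 0.25
grid_mask_radius_cells: 3
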