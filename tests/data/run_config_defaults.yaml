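channels: {}
k_global: 2.0
k_roi: 1.5
min_dendrite_um: 50.0
min_overlap_px: 2
min_overlap_vox: 1
out_dir: results
proximity_nm: 200.0
scene: null
seed: 0
segmentation:
  gaussfit_sd: 1.5
  global_k: 2.0
  max_radius: 20
  max_voxels: 20000
  maxima_radius_xy: 5
  maxima_radius_z: 2
  min_voxels: 3
  smooth_sigma_px: 0.8
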