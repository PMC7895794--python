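# Example run configuration for the `mrnlm` pipeline.
# Every key is optional; omitted keys fall back to the documented defaults
# (the full 5:1 six-sphere phantom with twelve auxiliary reconstructions).

seed: 1
log_level: INFO

phantom:
  cylinder_radius_mm: 100.0
  cylinder_height_mm: 180.0
  sphere_diameters_mm: [11.89, 14.43, 17.69, 21.79, 26.82, 33.27]
  background_activity: 3.6     # kBq/ml
  sphere_activity: 18.4        # kBq/ml, 5:1 contrast
  voxel_size_mm: [2.0, 2.0, 3.0]
  # sphere_centers_mm: explicit [[x, y, z], ...] placements; default is a
  # 55 mm circle in the central transaxial plane

emulation:
  psf_fwhm_mm: 5.0             # base resolution blur at 42 effective iterations
  noise_sigma: 0.13            # background noise SD / background activity
  noise_correlation_fwhm_mm: 4.0
  effective_iteration_ref: 42
  noise_exponent: 0.5
  blur_exponent: 0.3

target: {iterations: 2, subsets: 21}

# Omit `auxiliaries` for the default twelve iteration/subset pairs:
# 2i:24s 2i:28s 3i:14s 3i:12s 3i:21s 4i:12s 4i:8s 5i:8s 5i:7s 5i:6s 6i:7s 7i:6s

filters:
  - {method: gaussian, fwhm_mm: 6.0}
  - {method: nlm, h: 0.3, patch_radius: [2, 2, 0], search_radius: [5, 5, 1]}
  - {method: mrnlm, h: 0.3, include_target: true}
  - {method: mr_average, include_target: true}
  # the bilateral filter is available but slow at sigma_spatial 3.8 on a
  # full phantom grid:
  # - {method: bilateral, sigma_spatial: 3.8, sigma_intensity: 0.35}
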