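# 0.67 mm isotropic thin-slab protocol (visual / motor cortex slab)
fov_mm: [192.0, 192.0, 16.0]
matrix: [288, 288, 24]
shots_per_volume: 40
r_inplane: 1
te_ms: 23.0
tr_shot_ms: 58.0
echo_spacing_ms: 1.22
flip_angle_deg: 13.0
n_navigators: 3
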