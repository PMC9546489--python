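# 0.8 x 0.8 x 2.0 mm anisotropic whole-brain protocol
fov_mm: [192.0, 192.0, 132.0]
matrix: [240, 240, 66]
shots_per_volume: 48
r_inplane: 2
te_ms: 22.0
tr_shot_ms: 50.0
echo_spacing_ms: 1.02
flip_angle_deg: 13.0
n_navigators: 3
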