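length_90th
width_midbody_norm_10th
curvature_hips_abs_90th
curvature_head_abs_90th
motion_mode_paused_fraction
motion_mode_paused_frequency
d_curvature_hips_abs_90th
d_curvature_head_abs_90th
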