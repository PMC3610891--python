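act_max: 1.0
act_min: -0.16
detector_bias: -1.86
input_activation: 1.0
max_cycles: 500
monitoring_activation: 0.0
noise_sd: 0.0085
response_threshold: 0.14
step_size: 0.0076
w_detector_pm: 3.26
w_input_detector: 1.0
w_input_ongoing: 0.51
w_lateral_detector: -0.99
w_lateral_output: -1.23
w_monitor_detector: 0.85
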