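# Four-echo labeled-cell phantom: five tubes spanning the labeling series.
echo_times: [4.9, 13.6, 22.3, 57.0]
grid: [64, 64]
tube_radius: 5.0
relaxivity_r2star: 324.0
noise_sigma: 20.0
tubes:
  - {label: unlabeled, iron_concentration: 0.0}
  - {label: fion12.5, iron_concentration: 12.5}
  - {label: fion25, iron_concentration: 25.0}
  - {label: fion50, iron_concentration: 50.0}
  - {label: fion100, iron_concentration: 100.0}
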