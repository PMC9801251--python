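{
  "out_dir": "demo_out",
  "seed": 7,
  "cohort": {"n_hc": 4, "n_ma": 4},
  "phantom": {"noise_sd": 0.01},
  "task": {"trials_per_cell": 1},
  "segmentation": {},
  "stats": {"correction": "none", "sided": "two"},
  "write_nifti": false,
  "verbosity": 1
}
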