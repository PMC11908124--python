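{
  "input": {
    "kind": "synthetic",
    "n_residues": 60,
    "geometry": "ideal-helix",
    "amplitude": 0.5,
    "n_frames": 2000,
    "correlation": {
      "kind": "block",
      "blocks": [
        [
          0,
          1,
          2,
          3,
          4,
          5,
          6,
          7,
          8,
          9,
          10,
          11,
          12,
          13,
          14,
          15,
          16,
          17,
          18,
          19,
          20,
          21,
          22,
          23,
          24,
          25,
          26,
          27,
          28,
          29
        ],
        [
          30,
          31,
          32,
          33,
          34,
          35,
          36,
          37,
          38,
          39,
          40,
          41,
          42,
          43,
          44,
          45,
          46,
          47,
          48,
          49,
          50,
          51,
          52,
          53,
          54,
          55,
          56,
          57,
          58,
          59
        ]
      ],
      "rho_in": 0.6,
      "rho_out": 0.2
    },
    "planted_chain": {
      "nodes": [
        50,
        47,
        43,
        40,
        36,
        33,
        29,
        26,
        22
      ],
      "rho": 0.95
    },
    "seeds": [
      1,
      2,
      3
    ]
  },
  "selection": "calpha",
  "equilibration_fraction": 0.5,
  "network": {
    "contact_cutoff": 8.0,
    "correlation_threshold": 0.5,
    "path_use_contact_gate": true
  },
  "paths": {
    "source": 50,
    "sink": 22,
    "k": 100,
    "bin_width": 0.05
  },
  "interactions": {
    "pairs": [
      {
        "group_a": "resid=43",
        "group_b": "resid=57",
        "label": "beta3K-alphaCE-analog",
        "cutoff": 30.0
      }
    ]
  },
  "energetics": {
    "n_res_a": 3,
    "n_res_b": 3,
    "separation": 5.0,
    "charges": [
      1.0,
      0.0,
      -1.0,
      -1.0,
      0.0,
      1.0
    ],
    "lj_epsilon": [
      0.1,
      0.1,
      0.1,
      0.1,
      0.1,
      0.1
    ],
    "temperature": 310.0
  },
  "output_dir": "allodyn_out",
  "superpose": false
}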