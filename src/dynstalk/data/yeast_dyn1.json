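{
  "scheme": "yeast_dyn1",
  "description": "Package-defined rigid-body residue ranges for the S. cerevisiae cytoplasmic dynein (Dyn1) motor domain, numbering as in the AMPPNP crystal structure. Approximate boundaries chosen to be consistent with the catalytic motif positions; stalk, buttress and MTBD fall outside the 13 bodies. Override with a custom JSON for other models.",
  "subdomains": {
    "linker": [[1361, 1772]],
    "AAA1L": [[1773, 1980]],
    "AAA1s": [[1981, 2075]],
    "AAA2L": [[2076, 2310]],
    "AAA2s": [[2311, 2395]],
    "AAA3L": [[2396, 2625]],
    "AAA3s": [[2626, 2720]],
    "AAA4L": [[2721, 3000]],
    "AAA4s": [[3345, 3440]],
    "AAA5L": [[3441, 3610]],
    "AAA5s": [[3745, 3845]],
    "AAA6L": [[3846, 4000]],
    "AAA6s": [[4001, 4092]]
  },
  "other_regions": {
    "CC1": [[3008, 3125]],
    "MTBD": [[3126, 3230]],
    "CC2": [[3231, 3344]],
    "buttress": [[3611, 3744]]
  },
  "motifs": {
    "walker_a": 1802,
    "q_motif": 1829,
    "walker_b": 1848,
    "sensor_ii": 1971,
    "insert_loop": 2116,
    "arginine_finger": 2209
  },
  "triples": {
    "AAA1L_axis": [1802, 1848, 1829],
    "AAA2L_axis": [2209, 1971, 2116]
  },
  "anchors": {
    "CC1": [3008, 3125],
    "CC2": [3231, 3344]
  }
}
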