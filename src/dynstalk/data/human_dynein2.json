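{
  "scheme": "human_dynein2",
  "description": "Package-defined rigid-body residue ranges for the human cytoplasmic dynein-2 motor domain, numbering as in the ADP-vanadate crystal structure. Approximate boundaries chosen to be consistent with the catalytic motif positions; stalk, buttress and MTBD fall outside the 13 bodies. Override with a custom JSON for other models.",
  "subdomains": {
    "linker": [[1260, 1665]],
    "AAA1L": [[1666, 1875]],
    "AAA1s": [[1876, 1968]],
    "AAA2L": [[1969, 2205]],
    "AAA2s": [[2206, 2290]],
    "AAA3L": [[2291, 2520]],
    "AAA3s": [[2521, 2615]],
    "AAA4L": [[2616, 2890]],
    "AAA4s": [[3235, 3330]],
    "AAA5L": [[3331, 3500]],
    "AAA5s": [[3641, 3740]],
    "AAA6L": [[3741, 3895]],
    "AAA6s": [[3896, 4000]]
  },
  "other_regions": {
    "CC1": [[2891, 3010]],
    "MTBD": [[3011, 3110]],
    "CC2": [[3111, 3234]],
    "buttress": [[3501, 3640]]
  },
  "motifs": {
    "walker_a": 1695,
    "walker_b": 1741,
    "sensor_ii": 1867,
    "insert_loop": 2020,
    "arginine_finger": 2109
  },
  "triples": {
    "AAA2L_axis": [2109, 1867, 2020]
  },
  "anchors": {
    "CC1": [2891, 3010],
    "CC2": [3111, 3234]
  }
}
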