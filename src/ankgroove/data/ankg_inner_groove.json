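{
  "protein": "AnkG",
  "comment": "Inner-groove annotation of the AnkG ANK-repeat region (author numbering of the 275-571 construct). Frames are anchored at the hairpin-tip hydrophobic position of each repeat; layer residue identities are those resolved in the deposited complex structure.",
  "first_residue_number": 275,
  "last_residue_number": 571,
  "frames": [
    {"start": 277, "period": 33, "label": "R8"},
    {"start": 310, "period": 33, "label": "R9"},
    {"start": 343, "period": 33, "label": "R10"},
    {"start": 376, "period": 33, "label": "R11"},
    {"start": 409, "period": 33, "label": "R12"},
    {"start": 442, "period": 33, "label": "R13"},
    {"start": 475, "period": 33, "label": "R14"}
  ],
  "layers": {
    "phi1": {"277": "I", "310": "L", "343": "L", "376": "L", "409": "F", "442": "L"},
    "phi2": {"282": "V", "315": "C", "348": "M", "381": "V", "414": "I", "447": "V"},
    "rho1": {"308": "D", "341": "N", "374": "D"},
    "rho2": {"318": "R", "351": "Q", "384": "H"}
  }
}
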