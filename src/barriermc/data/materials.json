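{
  "concrete": {
    "density": 2.35,
    "fractions": {
      "H": 0.0056, "O": 0.4983, "Na": 0.0171, "Mg": 0.0024, "Al": 0.0456,
      "Si": 0.3158, "S": 0.0012, "K": 0.0192, "Ca": 0.0826, "Fe": 0.0122
    }
  },
  "air": {
    "density": 1.205e-3,
    "fractions": {
      "C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827
    }
  }
}
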