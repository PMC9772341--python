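{
  "comment": "Named residue sets used by the feature table (textbook definitions; user-overridable). The five-class grouping used for positional chi-squared tests lives under 'chi2_classes' and partitions the 20 canonical residues exactly.",
  "feature_classes": {
    "acidic": "DE",
    "basic": "KRH",
    "non_polar": "AGVLIMFWP",
    "polar": "STNQYCHDEKR",
    "acyclic": "AGVLIMSTNQDEKRC",
    "cyclic": "FWYHP",
    "aliphatic": "AGVLI",
    "aromatic": "FWYH",
    "charged": "DEKR",
    "efmr": "EFMR",
    "tiny": "AGPS",
    "small": "TD",
    "ivywrel": "IVYWREL",
    "positive": "RK",
    "negative": "DE"
  },
  "chi2_classes": {
    "aliphatic": "AGVLIMCP",
    "aromatic": "FWYH",
    "positive": "RK",
    "negative": "DE",
    "polar": "NQST"
  }
}
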