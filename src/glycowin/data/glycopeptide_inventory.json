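[
  {
    "protein": "sex hormone-binding globulin",
    "peptide": "SHEIWTHSCPQSPGNGTDASHLDVDQALNR",
    "glycoforms": ["A2G2", "A2G2F1", "A2G2S1", "A2G2S2", "A2G2S1F1",
                   "A2G2S2F1", "A3G3", "A3G3F1", "A3G3S2", "A3G3S3"]
  },
  {
    "protein": "haptoglobin",
    "peptide": "VVLHPNYSQVDIGLIK",
    "glycoforms": ["A2G2", "A2G2F1", "A2G2S1", "A2G2S2", "A2G2S1F1",
                   "A2G2S2F1", "A3G3", "A3G3F1", "A3G3S1", "A3G3S2", "A3G3S3"]
  },
  {
    "protein": "haptoglobin",
    "peptide": "MVSHHNLTTGATLINEQWLLTTAK",
    "glycoforms": ["A2G2", "A2G2F1", "A2G2S1", "A2G2S2", "A2G2S1F1",
                   "A3G3", "A3G3F1", "A3G3S1", "A3G3S2", "A3G3S3"]
  },
  {
    "protein": "hemopexin",
    "peptide": "SWPAVGNCSSALR",
    "glycoforms": ["A2G2", "A2G2F1", "A2G2S1", "A2G2S2", "A2G2S2F1",
                   "A3G3", "A3G3F1", "A3G3S1", "A3G3S2", "A3G3S3"]
  },
  {
    "protein": "hemopexin",
    "peptide": "ALPQPQNVTSLLGCTH",
    "glycoforms": ["A2G2", "A2G2F1", "A2G2S1", "A2G2S2", "A2G2S1F1",
                   "A2G2S2F1", "A3G3", "A3G3F1"]
  }
]
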