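{
  "LCPDCPLLAPLNDSR": {
    "A2G2S2": [54.8, 59.6],
    "A3G3": [32.5, 33.3],
    "A3G3S2": [57.0, 61.0],
    "A3G3S3": [67.5, 71.9]
  },
  "RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR": {
    "A2G2S1": [49.2, 52.1],
    "A2G2S2": [66.2, 72.0],
    "A3G3": [39.2, 40.2],
    "A3G3S1": [50.7, 52.3],
    "A3G3S3": [81.5, 86.8]
  },
  "VVHAVEVALATFNAESNGSYLQLVEISR": {
    "A3G3": [35.6, 36.5],
    "A3G3S3": [73.9, 78.7]
  }
}
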