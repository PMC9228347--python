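peptide_id,glycoform,rt_min
LCPDCPLLAPLNDSR,A2G2,30.2
LCPDCPLLAPLNDSR,A2G2S2,55.8
LCPDCPLLAPLNDSR,A3G3,32.9
LCPDCPLLAPLNDSR,A3G3S2,59.4
LCPDCPLLAPLNDSR,A3G3S3,68.1
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A2G2,36.5
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A2G2S1,49.8
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A2G2S2,67.1
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A3G3,39.6
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A3G3S1,52.1
RPTGEVYDIEIDTLETTCHVLDPTPLANCSVR,A3G3S3,84.1
VVHAVEVALATFNAESNGSYLQLVEISR,A2G2,33.1
VVHAVEVALATFNAESNGSYLQLVEISR,A3G3,35.8
VVHAVEVALATFNAESNGSYLQLVEISR,A3G3S3,75.7
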