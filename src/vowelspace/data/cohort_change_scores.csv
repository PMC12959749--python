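speaker,d_aavs,d_qvsa,d_vsahull,wcab_ae_gain
DS01,-5819.27,-620939.77,-214417.43,-2
DS02,66801.69,-100302.82,418538.12,-1
DS03,-27110.35,-101581.55,-304131.37,-7
DS06,-8502.12,-143924.48,-57975.48,3
DS07,103.02,-55755.14,179333.30,14
DS08,11885.86,-71054.22,56110.26,2
DS09,-47592.38,-104539.43,-229482.71,3
DS10,12218.59,-55715.40,164950.74,0
DS11,9143.78,81825.20,174607.30,3
DS13,-2499.41,-335528.19,-181308.92,4
DS15,-36613.26,11140.77,-126573.86,2
DS17,18184.57,183942.80,36913.09,-3
DS18,-6629.19,41777.69,71942.63,0
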