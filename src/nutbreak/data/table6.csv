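result,T,V,MC,D,DT,SEC,HR,WR,SR
prediction,54.9,3.66,10.9,3,585.1,12.86,81.7,43.7,99.8
validation,54.9,3.66,10.9,3,565,12.38,83.8,45.2,96
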