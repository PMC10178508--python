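algorithm,DT_R2,DT_RMSE,SEC_R2,SEC_RMSE,HR_R2,HR_RMSE,WR_R2,WR_RMSE,SR_R2,SR_RMSE
BP,0.950,33,0.968,0.363,0.979,1.652,0.970,1.187,0.956,2.525
GA-ANN,0.996,22.176,0.998,0.279,0.990,1.471,0.991,0.926,0.993,1.250
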