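subject_id,age,sex,race_ethnicity,iq,mother_education,smoking,scanner_id,lam_true,rho_true,tau_true,pcc_true
S001,30.154771,F,2,88.7,15.8,0,2,1.281911,0.658886,3.744426,2.763216
S002,47.555047,M,1,111.0,18.0,1,1,1.669896,0.5896,2.984104,1.945011
S003,35.452245,M,3,105.0,15.0,0,2,1.169313,0.568067,3.910302,2.142748
S004,47.893645,F,2,125.4,12.4,0,2,1.935215,0.661793,6.073728,2.051424
S005,37.871951,F,1,107.6,14.4,1,1,1.311118,0.589343,3.307958,2.234644
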