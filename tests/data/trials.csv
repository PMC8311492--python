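subject_id,trial_index,gain,loss,response,rt
S001,1,12.0,19.0,4.0,1.079068
S001,2,10.0,9.0,2.0,1.859359
S001,3,10.0,17.0,3.0,1.529744
S001,4,38.0,12.0,1.0,0.687327
S001,5,24.0,14.0,1.0,1.529113
S001,6,40.0,14.0,2.0,0.931187
S001,7,12.0,11.0,3.0,0.824597
S001,8,26.0,7.0,2.0,1.753576
S001,9,18.0,15.0,1.0,1.992872
S001,10,10.0,15.0,4.0,2.644851
S001,11,24.0,13.0,1.0,0.96397
S001,12,14.0,14.0,4.0,1.362595
S001,13,10.0,14.0,3.0,1.776693
S001,14,26.0,19.0,4.0,1.091359
S001,15,18.0,12.0,3.0,1.230425
S001,16,14.0,7.0,2.0,0.839802
S001,17,36.0,17.0,2.0,2.321745
S001,18,24.0,19.0,3.0,1.503956
S001,19,24.0,7.0,1.0,1.239266
S001,20,24.0,18.0,4.0,1.337776
S002,1,12.0,19.0,3.0,1.712297
S002,2,10.0,9.0,3.0,1.113449
S002,3,10.0,17.0,3.0,0.951205
S002,4,38.0,12.0,1.0,0.906757
S002,5,24.0,14.0,3.0,1.441897
S002,6,40.0,14.0,1.0,1.142894
S002,7,12.0,11.0,4.0,0.89196
S002,8,26.0,7.0,2.0,1.02386
S002,9,18.0,15.0,4.0,1.525837
S002,10,10.0,15.0,4.0,0.980037
S002,11,24.0,13.0,4.0,0.980364
S002,12,14.0,14.0,4.0,1.523778
S002,13,10.0,14.0,4.0,1.234777
S002,14,26.0,19.0,4.0,2.757176
S002,15,18.0,12.0,3.0,1.078736
S002,16,14.0,7.0,4.0,1.374551
S002,17,36.0,17.0,1.0,1.730326
S002,18,24.0,19.0,4.0,2.7864
S002,19,24.0,7.0,2.0,2.138698
S002,20,24.0,18.0,3.0,0.745386
S003,1,12.0,19.0,4.0,1.658144
S003,2,10.0,9.0,4.0,1.414377
S003,3,10.0,17.0,4.0,1.35153
S003,4,38.0,12.0,1.0,0.852859
S003,5,24.0,14.0,2.0,0.634089
S003,6,40.0,14.0,1.0,0.647095
S003,7,12.0,11.0,3.0,0.908506
S003,8,26.0,7.0,1.0,0.418388
S003,9,18.0,15.0,3.0,2.119985
S003,10,10.0,15.0,4.0,1.059587
S003,11,24.0,13.0,1.0,1.02916
S003,12,14.0,14.0,4.0,1.348737
S003,13,10.0,14.0,4.0,1.700262
S003,14,26.0,19.0,4.0,0.99939
S003,15,18.0,12.0,2.0,1.379097
S003,16,14.0,7.0,2.0,1.129478
S003,17,36.0,17.0,2.0,1.512101
S003,18,24.0,19.0,3.0,2.003379
S003,19,24.0,7.0,2.0,0.632543
S003,20,24.0,18.0,3.0,1.167
S004,1,12.0,19.0,4.0,1.44169
S004,2,10.0,9.0,3.0,1.353105
S004,3,10.0,17.0,4.0,0.746307
S004,4,38.0,12.0,2.0,1.330213
S004,5,24.0,14.0,4.0,1.859503
S004,6,40.0,14.0,3.0,1.722537
S004,7,12.0,11.0,4.0,1.608757
S004,8,26.0,7.0,2.0,2.429921
S004,9,18.0,15.0,3.0,1.807368
S004,10,10.0,15.0,3.0,1.369872
S004,11,24.0,13.0,3.0,1.958898
S004,12,14.0,14.0,4.0,1.290805
S004,13,10.0,14.0,4.0,1.220118
S004,14,26.0,19.0,3.0,1.61219
S004,15,18.0,12.0,3.0,1.990918
S004,16,14.0,7.0,4.0,2.616348
S004,17,36.0,17.0,3.0,1.085918
S004,18,24.0,19.0,4.0,1.747805
S004,19,24.0,7.0,1.0,1.21315
S004,20,24.0,18.0,4.0,1.027883
S005,1,12.0,19.0,1.0,1.151246
S005,2,10.0,9.0,2.0,1.769737
S005,3,10.0,17.0,1.0,1.03106
S005,4,38.0,12.0,2.0,1.412565
S005,5,24.0,14.0,1.0,1.434994
S005,6,40.0,14.0,2.0,1.559171
S005,7,12.0,11.0,1.0,2.539558
S005,8,26.0,7.0,2.0,0.714382
S005,9,18.0,15.0,1.0,0.73872
S005,10,10.0,15.0,2.0,1.385804
S005,11,24.0,13.0,1.0,0.916641
S005,12,14.0,14.0,2.0,1.609041
S005,13,10.0,14.0,1.0,1.13167
S005,14,26.0,19.0,2.0,1.7102
S005,15,18.0,12.0,1.0,1.797832
S005,16,14.0,7.0,2.0,1.075063
S005,17,36.0,17.0,1.0,1.616253
S005,18,24.0,19.0,2.0,0.905275
S005,19,24.0,7.0,1.0,2.272402
S005,20,24.0,18.0,2.0,1.218628
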