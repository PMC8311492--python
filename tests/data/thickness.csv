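subject_id,age,sex,race_ethnicity,scanner_id,etiv,qc_pass,insula_lh_thickness,insula_lh_volume,insula_rh_thickness,insula_rh_volume,medialorbitofrontal_lh_thickness,medialorbitofrontal_lh_volume,medialorbitofrontal_rh_thickness,medialorbitofrontal_rh_volume,lateralorbitofrontal_lh_thickness,lateralorbitofrontal_lh_volume,lateralorbitofrontal_rh_thickness,lateralorbitofrontal_rh_volume,rostralanteriorcingulate_lh_thickness,rostralanteriorcingulate_lh_volume,rostralanteriorcingulate_rh_thickness,rostralanteriorcingulate_rh_volume,caudalanteriorcingulate_lh_thickness,caudalanteriorcingulate_lh_volume,caudalanteriorcingulate_rh_thickness,caudalanteriorcingulate_rh_volume,posteriorcingulate_lh_thickness,posteriorcingulate_lh_volume,posteriorcingulate_rh_thickness,posteriorcingulate_rh_volume,superiorfrontal_lh_thickness,superiorfrontal_lh_volume,superiorfrontal_rh_thickness,superiorfrontal_rh_volume,precentral_lh_thickness,precentral_lh_volume,precentral_rh_thickness,precentral_rh_volume,lateraloccipital_lh_thickness,lateraloccipital_lh_volume,lateraloccipital_rh_thickness,lateraloccipital_rh_volume,precuneus_lh_thickness,precuneus_lh_volume,precuneus_rh_thickness,precuneus_rh_volume
S001,30.154771,F,2,2,1560725.064514,True,3.064108,6457.153025,3.157954,6546.918172,2.630084,5261.038068,2.523524,5526.404895,2.713403,7205.907036,2.778613,7696.994073,3.063087,2246.630577,3.029652,2263.864466,2.83202,1921.050093,2.850265,1871.419078,2.760865,2965.11329,2.756698,3256.861756,2.962064,21703.129513,2.9046,20691.434905,2.642142,13606.16704,2.724641,12434.009451,2.359218,11190.375225,2.331332,11339.037377,2.509119,9740.369138,2.524197,9611.349397
S002,47.555047,M,1,1,1521319.100777,True,2.93264,6328.076238,2.892558,6279.349708,2.389533,4799.115739,2.293126,5211.539417,2.495458,7514.090234,2.599359,7474.512078,2.962264,2527.871125,2.881659,2421.0895,2.653816,2014.077038,2.633051,2142.280955,1.933917,3103.592545,1.942415,3244.304599,2.814485,22413.987188,2.69368,20630.455157,2.529018,14521.173127,2.535862,12721.590194,2.142052,10919.055736,2.1588,11017.647457,2.344641,10231.623512,2.324808,9376.8627
S003,35.452245,M,3,2,1575016.978352,True,3.117053,6653.320037,3.175328,6549.91948,2.533152,5005.377027,2.644851,5137.579434,2.68918,7055.309384,2.756674,6821.14495,3.056905,2442.336521,2.966252,2425.04084,2.763226,1800.469103,2.69249,1865.032572,2.149183,2915.31038,2.124943,3293.736235,2.908349,21617.480325,2.976195,21367.598931,2.604778,13163.825166,2.622016,13508.3622,2.197772,9998.223463,2.165189,11481.268032,2.552588,10621.840588,2.540364,9686.970285
S004,47.893645,F,2,2,1561411.873112,True,3.134052,6840.139585,2.965657,6587.687877,2.489354,5479.682856,2.559074,4934.164155,2.488148,7844.293842,2.644855,7233.16517,2.991307,2476.794958,2.893307,2334.210711,2.703136,1967.231675,2.778155,2099.655715,2.065284,3061.776706,2.05001,3220.281501,2.760468,21215.992247,2.760633,21058.436797,2.64562,14085.376598,2.680553,13592.682289,2.178322,11331.869462,2.397316,11468.128747,2.372149,10348.394227,2.344407,8722.076906
S005,37.871951,F,1,1,1541114.152125,True,2.969812,6372.468555,2.972011,6862.904231,2.433334,5389.034013,2.498125,5025.076582,2.531506,7412.994838,2.587695,7808.053131,2.90397,2495.381388,2.837714,2551.75547,2.610507,2005.909938,2.757077,2097.386702,2.223787,3258.834719,2.210721,3097.275382,2.774451,21116.245778,2.750258,21088.289604,2.664016,12686.085133,2.652569,12920.235557,2.131949,10512.323973,2.178006,10603.34956,2.392342,9593.149653,2.376478,10135.387967
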