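line_id,patient,site,run,architecture,total_traps,unbroken_traps,n_timepoints,n_1to0,n_0to1,n_1to1,n_2to1,n_3to1,n_other,n_broken,s24_1to0,s24_0to1,s24_1to1,s24_2to1,s24_3to1
HN1,HN137,metastatic,1,13x29+13x30,767,739,73,6,40,243,66,7,377,28,0.9167,1.00,0.9732,0.9512,1.00
HN1,HN137,metastatic,2,13x29+13x30,767,669,73,6,13,233,139,45,233,98,,,,,
HN2,HN120,metastatic,1,15x30+15x31,915,763,73,9,33,400,105,32,184,152,1.00,0.8421,0.8766,0.8407,0.9063
HN2,HN120,metastatic,2,30x29,870,822,73,32,24,386,165,32,183,48,,,,,
HN3,HN159,metastatic,1,30x29,870,806,70,9,21,426,127,17,206,64,1.00,0.9775,0.9064,0.8535,0.9231
HN3,HN159,metastatic,2,15x30+15x31,915,821,73,13,68,279,112,9,340,94,,,,,
HN4,HN159,primary,1,30x29,870,848,73,8,13,177,129,45,441,22,1.00,1.00,0.8588,0.9070,0.8667
HN4,HN159,primary,2,30x29,870,651,73,69,91,213,79,12,187,219,,,,,
HN5,HN120,primary,1,26x28,728,669,73,7,7,138,179,39,299,59,0.9286,0.8889,0.3439,0.3308,0.3693
HN5,HN120,primary,2,15x30+15x31,915,818,73,7,11,83,87,26,604,97,,,,,
HN6,HN160,primary,1,26x28,728,725,73,28,187,271,82,7,150,3,0.9367,0.9223,0.8247,0.7154,0.6316
HN6,HN160,primary,2,26x28,728,503,73,51,79,117,48,12,196,225,,,,,
HN7,HN160,metastatic,1,13x29+13x30,767,737,73,26,109,277,108,18,199,30,0.9666,0.8877,0.8426,0.8572,0.8070
HN7,HN160,metastatic,2,13x29+13x30,767,730,73,4,87,244,109,39,247,37,,,,,
HN8,HN148,primary,1,15x30+15x31,915,868,73,6,11,286,146,44,375,47,1.00,0.8571,0.8534,0.855,
HN8,HN148,primary,2,13x29+13x30,767,745,73,29,143,294,54,8,217,22,,,,,
HN9,HN148,metastatic,1,30x29,870,733,73,18,248,263,24,1,179,137,1.00,0.9960,0.9924,1.00,1.00
HN10,HN137,primary,1,15x30+15x31,915,837,73,15,5,274,188,39,316,78,1.00,1.00,0.7409,0.7103,0.6441
HN10,HN137,primary,2,15x30+15x31,915,702,73,15,13,251,102,20,301,213,,,,,
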