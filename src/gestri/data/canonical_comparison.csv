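gw,trimester,harel_p95,study_p95,diff_p95,harel_p75,study_p75,diff_p75,harel_p50,study_p50,diff_p50,mean_diff_by_gw,diff_by_trimester
4,1,75,71.8,-3.2,64,61.0,-3.0,58,54.3,-3.7,-3.3,-1.5
6,1,70,67.3,-2.7,60,58.5,-1.5,54,52.4,-1.6,-1.9,-1.5
8,1,65,63.6,-1.4,56,55.8,-0.2,50,50.2,0.2,-0.5,-1.5
10,1,61,60.6,-0.4,53,53.2,0.2,48,48.0,0.0,-0.1,-1.5
12,1,61,58.2,-2.8,52,50.7,-1.3,47,45.8,-1.2,-1.8,-1.5
14,2,59,56.3,-2.7,51,48.5,-2.5,46,43.9,-2.1,-2.4,-4.1
16,2,59,55.0,-4.0,50,46.8,-3.2,45,42.2,-2.8,-3.3,-4.1
18,2,58,54.1,-3.9,49,45.6,-3.4,45,41.0,-4.0,-3.8,-4.1
20,2,59,53.6,-5.4,50,44.9,-5.1,45,40.2,-4.8,-5.1,-4.1
22,2,58,53.5,-4.5,50,44.8,-5.2,44,39.8,-4.2,-4.6,-4.1
24,2,59,53.6,-5.4,49,45.2,-3.8,45,39.9,-5.1,-4.8,-4.1
26,2,59,54.0,-5.0,50,46.1,-3.9,45,40.5,-4.5,-4.5,-4.1
28,3,59,54.7,-4.3,50,47.3,-2.7,44,41.4,-2.6,-3.2,-4.0
30,3,59,55.4,-3.6,50,48.8,-1.2,44,42.6,-1.4,-2.1,-4.0
32,3,60,56.2,-3.8,50,50.3,0.3,45,44.0,-1.0,-1.5,-4.0
34,3,63,57.1,-5.9,52,51.7,-0.3,46,45.4,-0.6,-2.3,-4.0
36,3,66,58.0,-8.0,54,52.7,-1.3,48,46.8,-1.2,-3.5,-4.0
38,3,70,58.7,-11.3,57,53.1,-3.9,50,47.9,-2.1,-5.8,-4.0
40,3,76,59.4,-16.6,61,52.6,-8.4,53,48.6,-4.4,-9.8,-4.0
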