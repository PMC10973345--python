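gw,scr_p2_5,scr_p97_5,scr_median,scr_increment_pct,egfr_p2_5,egfr_p97_5,egfr_median,egfr_increment_pct
4,38.9,79.3,54.3,-1.7,72.7,148.6,107.6,9.0
5,36.9,77.1,53.4,-3.3,72.6,149.7,111.4,12.9
6,35.0,75.0,52.4,-5.2,73.9,152.2,115.8,17.3
7,33.3,72.9,51.3,-7.1,76.4,155.8,120.7,22.3
8,31.8,70.8,50.2,-9.1,79.9,160.2,125.9,27.6
9,30.5,68.8,49.1,-11.1,84.1,165.3,131.3,33.1
10,29.3,66.9,48.0,-13.1,88.8,170.8,136.8,38.6
11,28.3,65.1,46.9,-15.1,93.9,176.6,142.3,44.2
12,27.4,63.4,45.8,-17.1,99.1,182.5,147.6,49.6
13,26.6,61.9,44.8,-18.9,104.2,188.3,152.6,54.6
14,26.0,60.6,43.9,-20.5,109.3,193.9,157.4,59.5
15,25.5,59.4,43.0,-22.2,114.1,199.2,161.7,63.9
16,25.1,58.3,42.2,-23.6,118.5,204.0,165.6,67.8
17,24.8,57.4,41.6,-24.7,122.4,208.3,169.0,71.3
18,24.6,56.7,41.0,-25.8,125.7,212.0,171.8,74.1
19,24.5,56.2,40.5,-26.7,128.5,215.0,174.0,76.3
20,24.5,55.9,40.2,-27.2,130.5,217.2,175.6,77.9
21,24.5,55.7,40.0,-27.6,131.9,218.7,176.6,79.0
22,24.6,55.7,39.8,-28.0,132.6,219.5,177.0,79.4
23,24.8,55.8,39.8,-28.0,132.5,219.4,176.8,79.2
24,25.0,56.0,39.9,-27.8,131.8,218.5,176.0,78.4
25,25.2,56.4,40.1,-27.4,130.3,216.9,174.6,76.9
26,25.4,56.9,40.5,-26.7,128.3,214.6,172.7,75.0
27,25.7,57.5,40.9,-26.0,125.7,211.6,170.4,72.7
28,26.0,58.2,41.4,-25.1,122.7,208.0,167.6,69.8
29,26.2,58.9,41.9,-24.2,119.3,203.9,164.4,66.6
30,26.5,59.6,42.6,-22.9,115.6,199.4,161.0,63.2
31,26.8,60.3,43.2,-21.8,111.8,194.6,157.5,59.6
32,27.0,61.0,44.0,-20.4,108.0,189.7,153.8,55.9
33,27.2,61.6,44.7,-19.1,104.4,184.7,150.2,52.2
34,27.3,62.2,45.4,-17.8,101.1,179.9,146.8,48.8
35,27.4,62.6,46.1,-16.6,98.4,175.5,143.6,45.5
36,27.5,62.8,46.8,-15.3,96.4,171.5,140.9,42.8
37,27.4,62.8,47.4,-14.2,95.3,168.3,138.7,40.6
38,27.4,62.6,47.9,-13.3,95.5,166.0,137.3,39.1
39,27.2,62.0,48.4,-12.4,97.1,164.9,136.8,38.6
40,26.9,61.1,48.6,-12.0,100.5,165.2,137.4,39.2
41,26.5,59.8,48.7,-11.9,105.9,167.3,139.3,41.2
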