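group,T,V,MC,D,DT,SEC,HR,WR,SR
1,51.5,1.04,10.0,2,958.4,16.77,89.0,50.9,92.8
2,53.3,1.20,10.1,2,888.5,16.49,88.9,50.4,93.6
3,47.0,1.01,10.0,2,1082.2,16.78,88.8,51.2,89.5
4,44.7,1.50,11.1,2,974.0,14.77,86.2,48.4,86.8
5,52.5,3.59,23.2,2,137.9,1.84,48.8,24.9,68.2
6,43.1,1.02,10.0,2,1193.4,16.78,88.7,51.2,85.3
7,54.9,3.66,10.9,3,585.1,12.86,81.7,43.7,99.8
8,54.9,3.98,20.3,3,181.4,2.78,58.6,32.1,84.8
9,54.7,3.97,21.3,2,157.2,2.33,54.1,28.8,75.7
10,49.6,1.01,10.0,2,1012.0,16.79,88.9,51.0,91.6
11,53.4,3.83,17.4,2,264.8,4.70,69.2,38.3,85.3
12,54.7,3.85,23.9,2,109.6,1.29,47.8,23.8,66.1
13,54.2,3.25,25.0,3,103.9,1.08,56.8,29.3,69.3
14,52.5,2.27,16.0,2,407.9,7.45,75.9,41.6,87.3
15,54.9,3.13,17.0,2,299.7,5.65,72.3,39.5,87.0
16,50.6,2.16,10.2,2,847.7,15.48,87.5,49.1,92.9
17,47.7,1.97,12.8,2,696.3,11.68,82.5,45.4,88.3
18,54.9,3.82,24.2,2,102.8,1.15,47.3,23.3,64.6
19,52.5,2.92,12.9,2,535.3,10.54,82.1,44.9,91.9
20,43.6,1.39,14.2,2,729.8,10.64,80.2,44.0,82.1
21,49.8,3.38,12.4,2,573.7,10.85,82.0,44.6,91.3
22,43.6,1.02,10.1,2,1169.3,16.65,88.6,51.0,85.8
23,47.3,1.75,10.9,2,901.0,14.80,86.4,48.5,89.7
24,50.4,3.71,17.2,2,299.8,5.11,69.5,38.4,84.0
25,52.9,3.65,20.4,3,200.6,3.06,58.6,32.2,83.5
26,52.5,2.74,16.6,2,353.5,6.39,73.3,40.3,86.3
27,52.7,2.03,15.7,2,436.6,8.03,77.2,42.3,87.9
28,55.0,3.98,23.3,2,116.8,1.45,48.7,24.7,68.5
29,54.9,3.93,23.0,2,123.3,1.60,49.4,25.2,69.6
30,55.0,3.99,25.0,2,87.3,0.81,46.1,22.4,61.8
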