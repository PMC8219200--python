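generation,count,diameter_cm,length_cm,branch_angle_deg,gravity_angle_deg
0,1,1.8000,12.000,0,0
1,2,1.2200,4.760,33,20
2,4,0.8300,1.900,34,31
3,8,0.5600,0.760,22,43
4,16,0.4500,1.270,20,39
5,32,0.3500,1.070,18,39
6,64,0.2800,0.900,19,40
7,128,0.2300,0.760,22,36
8,256,0.1860,0.640,28,39
9,512,0.1540,0.540,22,45
10,1024,0.1300,0.460,33,43
11,2048,0.1090,0.390,34,45
12,4096,0.0950,0.330,37,45
13,8192,0.0820,0.270,39,60
14,16384,0.0740,0.230,39,60
15,32768,0.0660,0.200,51,60
16,65536,0.0600,0.165,45,60
17,131072,0.0540,0.141,45,60
18,262144,0.0500,0.117,45,60
19,524288,0.0470,0.099,60,60
20,1048576,0.0450,0.083,60,60
21,2097152,0.0430,0.070,60,60
22,4194304,0.0410,0.059,60,60
23,8388608,0.0410,0.050,60,60
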