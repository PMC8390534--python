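run_id,temperature_C,geniposide,glycine,time_min,yield_ugml
1,40,240,2,5,0.3594
2,40,280,4,45,0.5397
3,40,320,6,20,0.3821
4,40,360,8,30,0.4689
5,40,400,10,60,0.6185
6,40,440,12,120,1.0939
7,40,480,14,180,1.1687
8,50,240,4,20,0.3407
9,50,280,6,30,0.3767
10,50,320,8,60,0.5504
11,50,360,10,120,1.0579
12,50,400,12,180,1.4599
13,50,440,14,5,0.3821
14,50,480,2,45,0.4782
15,60,240,6,60,0.9764
16,60,280,8,120,1.9006
17,60,320,10,180,2.8435
18,60,360,12,5,0.3687
19,60,400,14,45,0.9110
20,60,440,2,20,0.4769
21,60,480,4,30,0.6559
22,70,240,8,180,14.0623
23,70,280,10,5,0.4221
24,70,320,12,45,1.6282
25,70,360,14,20,0.8335
26,70,400,2,30,1.0766
27,70,440,4,60,2.0489
28,70,480,6,120,4.7601
29,80,240,10,45,2.3413
30,80,280,12,20,1.0899
31,80,320,14,30,1.5226
32,80,360,2,60,2.7393
33,80,400,4,120,7.2509
34,80,440,6,180,20.9378
35,80,480,8,5,0.4582
36,90,240,12,30,2.5003
37,90,280,14,60,5.9153
38,90,320,2,120,9.7377
39,90,360,4,180,21.7658
40,90,400,6,5,0.6812
41,90,440,8,45,4.1444
42,90,480,10,20,2.0208
43,100,240,14,120,10.4910
44,100,280,2,180,20.3688
45,100,320,4,5,0.5811
46,100,360,6,45,4.6469
47,100,400,8,20,1.9807
48,100,440,10,30,3.2509
49,100,480,12,60,7.9320
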