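patient_id,pred_sel,pred_all,acc_sel,acc_all,sens_sel,sens_all,spec_sel,spec_all,channels_sel
1,100,100,97.28,100,93.66,100,100,100,4;11;16;18
2,100,75,54.27,30.85,50.00,38.02,56.40,27.27,5;6;8;11
3,100,67,77.89,70.51,70.91,62.81,81.07,74.00,4;8;14;16;18;19;20;23
4,100,50,80.79,76.82,45.45,24.79,84.71,82.60,8;10;14;17;18;19
5,100,50,58.19,55.19,90.12,46.88,38.65,60.27,1;7;9;13;16
6,100,75,66.04,58.38,71.19,59.27,57.02,56.82,6;9;14;16;18
7,100,50,83.61,80.17,99.17,0.00,80.50,96.20,4;11;16;18
8,100,100,95.73,65.56,87.19,74.38,100,62.40,8;14;17;19
9,100,100,69.01,61.98,34.71,68.60,72.82,61.25,4;11;16;18;20
10,75,75,65.97,44.03,80.17,74.10,60.64,61.98,4;8;11;16;18;20
11,100,0,84.55,71.98,50.41,0.00,88.34,47.70,3;4;7;8;10;17;21
14,33.3,33.3,61.67,60.27,32.51,18.73,70.41,72.73,1;2;3;5;7;9;23
15,100,42.9,75.48,63.87,69.42,22.41,80.33,97.02,1;7;17;10;16;22;CP2-Ref
16,100,100,69.97,69.83,100,100,54.96,54.75,1;2;5;7;9;10;15;16
17,100,100,45.45,46.38,100,87.60,37.66,40.50,1;9;12
18,75,75,71.63,66.39,42.77,50.00,86.05,74.59,4;7;13;20;22
19,100,100,94.86,96.05,90.08,100,95.45,95.56,4;6;14
20,100,75,94.63,87.02,90.63,88.43,96.34,86.42,3;4;6;7;12;15
21,50,50,69.35,49.44,42.15,23.14,75.39,55.28,4;7;13;19;20;22
22,100,100,88.55,80.05,24.79,22.31,99.17,89.67,1;2;9;12;23
23,100,100,87.40,100,96.69,100,59.50,100,8;10;14;17;18;19
24,80,80,48.91,49.44,67.27,76.03,33.61,27.27,3;5;9;11;12;23
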