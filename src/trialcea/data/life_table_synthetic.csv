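age,sex,race,expectancy_years
0,F,white,84.661
5,F,white,79.751
10,F,white,74.841
15,F,white,69.933
20,F,white,65.029
25,F,white,60.134
30,F,white,55.255
35,F,white,50.401
40,F,white,45.585
45,F,white,40.825
50,F,white,36.146
55,F,white,31.578
60,F,white,27.163
65,F,white,22.949
70,F,white,18.993
75,F,white,15.356
80,F,white,12.096
85,F,white,9.261
90,F,white,6.881
95,F,white,4.959
100,F,white,3.47
0,F,black,81.559
5,F,black,76.649
10,F,black,71.74
15,F,black,66.834
20,F,black,61.935
25,F,black,57.049
30,F,black,52.185
35,F,black,47.353
40,F,black,42.57
45,F,black,37.858
50,F,black,33.245
55,F,black,28.768
60,F,black,24.474
65,F,black,20.416
70,F,black,16.654
75,F,black,13.249
80,F,black,10.253
85,F,black,7.703
90,F,black,5.614
95,F,black,3.971
100,F,black,2.73
0,F,hispanic,86.34
5,F,hispanic,81.431
10,F,hispanic,76.521
15,F,hispanic,71.612
20,F,hispanic,66.706
25,F,hispanic,61.808
30,F,hispanic,56.922
35,F,hispanic,52.059
40,F,hispanic,47.228
45,F,hispanic,42.446
50,F,hispanic,37.736
55,F,hispanic,33.126
60,F,hispanic,28.654
65,F,hispanic,24.365
70,F,hispanic,20.314
75,F,hispanic,16.561
80,F,hispanic,13.165
85,F,hispanic,10.18
90,F,hispanic,7.643
95,F,hispanic,5.566
100,F,hispanic,3.933
0,F,other,85.191
5,F,other,80.282
10,F,other,75.372
15,F,other,70.463
20,F,other,65.558
25,F,other,60.662
30,F,other,55.781
35,F,other,50.924
40,F,other,46.103
45,F,other,41.336
50,F,other,36.646
55,F,other,32.065
60,F,other,27.631
65,F,other,23.393
70,F,other,19.406
75,F,other,15.732
80,F,other,12.428
85,F,other,9.545
90,F,other,7.116
95,F,other,5.145
100,F,other,3.611
0,M,white,79.643
5,M,white,74.733
10,M,white,69.824
15,M,white,64.921
20,M,white,60.026
25,M,white,55.148
30,M,white,50.294
35,M,white,45.479
40,M,white,40.721
45,M,white,36.043
50,M,white,31.479
55,M,white,27.067
60,M,white,22.859
65,M,white,18.909
70,M,white,15.28
75,M,white,12.028
80,M,white,9.203
85,M,white,6.833
90,M,white,4.922
95,M,white,3.441
100,M,white,2.342
0,M,black,76.541
5,M,black,71.631
10,M,black,66.725
15,M,black,61.827
20,M,black,56.942
25,M,black,52.078
30,M,black,47.247
35,M,black,42.465
40,M,black,37.754
45,M,black,33.144
50,M,black,28.671
55,M,black,24.381
60,M,black,20.329
65,M,black,16.575
70,M,black,13.178
75,M,black,10.191
80,M,black,7.652
85,M,black,5.573
90,M,black,3.939
95,M,black,2.707
100,M,black,1.814
0,M,hispanic,81.323
5,M,hispanic,76.413
10,M,hispanic,71.503
15,M,hispanic,66.598
20,M,hispanic,61.699
25,M,hispanic,56.814
30,M,hispanic,51.951
35,M,hispanic,47.121
40,M,hispanic,42.341
45,M,hispanic,37.633
50,M,hispanic,33.025
55,M,hispanic,28.557
60,M,hispanic,24.272
65,M,hispanic,20.228
70,M,hispanic,16.482
75,M,hispanic,13.095
80,M,hispanic,10.119
85,M,hispanic,7.592
90,M,hispanic,5.525
95,M,hispanic,3.902
100,M,hispanic,2.679
0,M,other,80.173
5,M,other,75.263
10,M,other,70.354
15,M,other,65.45
20,M,other,60.554
25,M,other,55.673
30,M,other,50.817
35,M,other,45.997
40,M,other,41.231
45,M,other,36.544
50,M,other,31.965
55,M,other,27.535
60,M,other,23.302
65,M,other,19.321
70,M,other,15.654
75,M,other,12.359
80,M,other,9.487
85,M,other,7.067
90,M,other,5.107
95,M,other,3.582
100,M,other,2.444
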