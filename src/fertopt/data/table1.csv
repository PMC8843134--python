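n_g,k_g,mg_g,fy_mean,fy_sem,fl_mean,fl_sem,nrps_mean,nrps_sem
0,0,0,42.1,2.52,9.63,0.47,5.77,0.29
0,0,50,43.8,2.14,10.4,0.47,6.23,0.29
0,0,100,45.25,3.97,11.77,0.52,6.1,0.2
0,100,0,52.37,5.76,12.27,0.32,6.1,0.2
0,100,50,50.1,2.31,12.2,0.32,6.3,0
0,100,100,50.6,1.35,12.5,0.35,6.57,0.13
0,200,0,52.9,3.1,13.83,0.68,6.9,0.2
0,200,50,53.5,2.02,14.33,0.88,7.1,0.2
0,200,100,53.5,1.71,13.03,0.52,7.2,0.1
0,300,0,54.4,2.91,13.4,0.65,8.1,0.2
0,300,50,56.1,1.57,14.8,0.44,8.2,0.1
0,300,100,60.25,2.38,14.6,0.4,8.43,0.13
100,0,0,62.1,2.39,14.1,0.99,8.53,0.39
100,0,50,61.45,2.68,13.93,0.22,9,0.17
100,0,100,63.52,2.79,15.2,0.47,9.43,0.47
100,100,0,91.2,12.24,21.47,0.64,11.33,0.49
100,100,50,85.44,7.1,22,0.32,11.43,0.13
100,100,100,92.4,5.97,21.57,0.64,11.2,0.1
100,200,0,100.85,5.09,21.2,0.82,12,0.17
100,200,50,102.15,6.07,21.27,0.88,12.7,0
100,200,100,83.55,11.14,17.47,0.93,9.3,0
100,300,0,82.95,10.95,18.67,1.53,9.77,0.29
100,300,50,69,4.46,18.4,1.07,10.23,0.79
100,300,100,89.5,11,22.13,0.78,11.77,0.47
200,0,0,83.65,2.28,17.6,0.98,9.23,0.29
200,0,50,84,6.59,17.88,0.9,10.3,0
200,0,100,79.1,2.54,18.77,0.41,10.1,0.1
200,100,0,78,1.15,19.77,0.85,10.7,0
200,100,50,86.05,1.92,19.57,0.45,10.77,0.29
200,100,100,83.7,4.69,20.23,0.41,11.43,0.47
200,200,0,98.8,9.13,21.9,0.92,12.2,0.1
200,200,50,107.3,6.04,25.27,0.38,13.77,0.29
200,200,100,113.4,3.96,25.23,0.47,14.2,0.1
200,300,0,116.1,6.26,23.47,0.27,12.9,0.2
200,300,50,119.1,6.75,24.3,0.56,13.23,0.47
200,300,100,111.5,4.6,24,0.21,12.77,0.29
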