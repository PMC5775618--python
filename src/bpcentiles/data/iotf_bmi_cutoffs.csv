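age,boys_25,girls_25,boys_30,girls_30
2.0,18.41,18.02,20.09,19.81
2.5,18.13,17.76,19.80,19.55
3.0,17.89,17.56,19.57,19.36
3.5,17.69,17.40,19.39,19.23
4.0,17.55,17.28,19.29,19.15
4.5,17.47,17.19,19.26,19.12
5.0,17.42,17.15,19.30,19.17
5.5,17.45,17.20,19.47,19.34
6.0,17.55,17.34,19.78,19.65
6.5,17.71,17.53,20.23,20.08
7.0,17.92,17.75,20.63,20.51
7.5,18.16,18.03,21.09,21.01
8.0,18.44,18.35,21.60,21.57
8.5,18.76,18.69,22.17,22.18
9.0,19.10,19.07,22.77,22.81
9.5,19.46,19.45,23.39,23.46
10.0,19.84,19.86,24.00,24.11
10.5,20.20,20.29,24.57,24.77
11.0,20.55,20.74,25.10,25.42
11.5,20.89,21.20,25.58,26.05
12.0,21.22,21.68,26.02,26.67
12.5,21.56,22.14,26.43,27.24
13.0,21.91,22.58,26.84,27.76
13.5,22.27,22.98,27.25,28.20
14.0,22.62,23.34,27.63,28.57
14.5,22.96,23.66,27.98,28.87
15.0,23.29,23.94,28.30,29.11
15.5,23.60,24.17,28.60,29.29
16.0,23.90,24.37,28.88,29.43
16.5,24.19,24.54,29.14,29.56
17.0,24.46,24.70,29.41,29.69
17.5,24.73,24.85,29.70,29.84
18.0,25.00,25.00,30.00,30.00
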