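site,season,metal,concentration,se
A,wet,As,<0.001,
A,wet,Cr,<0.001,
A,wet,Cu,12.74,1.53
A,wet,Fe,1148.75,110.38
A,wet,Zn,13.05,0.94
A,dry,As,<0.001,
A,dry,Cr,<0.001,
A,dry,Cu,13.71,0.69
A,dry,Fe,1337.12,76.76
A,dry,Zn,19.43,1.26
B,wet,As,<0.001,
B,wet,Cr,21.05,2.04
B,wet,Cu,12.94,0.69
B,wet,Fe,2548.26,133.68
B,wet,Zn,22.15,1.87
B,dry,As,<0.001,
B,dry,Cr,22.76,0.94
B,dry,Cu,13.55,1.12
B,dry,Fe,3470.18,527.42
B,dry,Zn,33.14,1.52
C,wet,As,1.05,0.28
C,wet,Cr,31.15,1.23
C,wet,Cu,28.45,2.42
C,wet,Fe,14438.02,1598.70
C,wet,Zn,58.90,3.48
C,dry,As,1.20,0.26
C,dry,Cr,45.46,2.99
C,dry,Cu,26.05,2.92
C,dry,Fe,13394.13,1742.30
C,dry,Zn,53.28,4.64
D,wet,As,2.32,0.41
D,wet,Cr,87.04,5.33
D,wet,Cu,48.70,1.93
D,wet,Fe,20204.70,2453.20
D,wet,Zn,65.74,4.51
D,dry,As,2.51,0.45
D,dry,Cr,99.81,3.89
D,dry,Cu,62.50,3.29
D,dry,Fe,23204.62,1902.50
D,dry,Zn,83.71,4.63
E,wet,As,3.25,0.88
E,wet,Cr,84.07,3.39
E,wet,Cu,44.93,2.57
E,wet,Fe,19510.45,1049.60
E,wet,Zn,70.42,2.25
E,dry,As,1.39,0.25
E,dry,Cr,79.17,2.62
E,dry,Cu,51.45,3.41
E,dry,Fe,17307.45,1207.80
E,dry,Zn,67.04,4.56
F,wet,As,2.31,0.49
F,wet,Cr,68.11,4.28
F,wet,Cu,70.42,4.77
F,wet,Fe,12490.37,2238.20
F,wet,Zn,69.02,5.90
F,dry,As,1.49,0.46
F,dry,Cr,49.11,5.24
F,dry,Cu,64.19,3.41
F,dry,Fe,13597.16,2700.20
F,dry,Zn,48.07,4.78
G,wet,As,1.05,0.22
G,wet,Cr,101.26,3.29
G,wet,Cu,70.93,4.71
G,wet,Fe,13108.43,2604.30
G,wet,Zn,37.05,1.64
G,dry,As,1.05,0.15
G,dry,Cr,94.17,4.37
G,dry,Cu,69.14,4.15
G,dry,Fe,11370.38,2282.20
G,dry,Zn,29.48,4.27
H,wet,As,2.75,0.53
H,wet,Cr,62.07,9.57
H,wet,Cu,99.04,3.42
H,wet,Fe,10406.75,1468.10
H,wet,Zn,31.90,3.32
H,dry,As,1.09,0.10
H,dry,Cr,55.42,6.32
H,dry,Cu,108.32,5.19
H,dry,Fe,9023.41,6411.20
H,dry,Zn,39.71,4.83
I,wet,As,<0.001,
I,wet,Cr,52.80,4.92
I,wet,Cu,100.47,5.94
I,wet,Fe,8307.38,964.07
I,wet,Zn,27.17,2.49
I,dry,As,<0.001,
I,dry,Cr,59.81,5.64
I,dry,Cu,110.18,5.92
I,dry,Fe,12370.16,3095.90
I,dry,Zn,33.41,3.72
J,wet,As,<0.001,
J,wet,Cr,52.07,3.84
J,wet,Cu,107.92,7.24
J,wet,Fe,13281.05,2964.90
J,wet,Zn,42.19,7.43
J,dry,As,<0.001,
J,dry,Cr,62.36,10.89
J,dry,Cu,102.70,10.68
J,dry,Fe,15290.12,3404.20
J,dry,Zn,39.71,10.49
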