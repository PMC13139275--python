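site,season,metal,cf,ef,igeo
A,wet,As,,,
A,wet,Cr,,,
A,wet,Cu,0.32,4.77,-2.24
A,wet,Fe,0.02,1.00,-5.95
A,wet,Zn,0.23,3.49,-2.69
A,dry,As,,,
A,dry,Cr,,,
A,dry,Cu,0.34,4.85,-2.13
A,dry,Fe,0.03,1.00,-5.73
A,dry,Zn,0.35,4.91,-2.12
B,wet,As,,,
B,wet,Cr,0.97,8.30,-0.63
B,wet,Cu,0.32,6.01,-2.21
B,wet,Fe,0.05,1.00,-4.80
B,wet,Zn,0.40,7.34,-1.93
B,dry,As,,,
B,dry,Cr,1.04,8.21,-0.53
B,dry,Cu,0.34,4.69,-2.15
B,dry,Fe,0.07,1.00,-4.36
B,dry,Zn,0.57,7.95,-1.39
C,wet,As,0.11,0.38,-3.76
C,wet,Cr,1.44,4.77,-0.06
C,wet,Cu,0.71,2.36,-1.08
C,wet,Fe,0.31,1.00,-2.30
C,wet,Zn,1.05,3.46,-0.51
C,dry,As,0.13,0.48,-3.51
C,dry,Cr,2.10,7.48,0.49
C,dry,Cu,0.65,2.33,-1.21
C,dry,Fe,0.28,1.00,-2.41
C,dry,Zn,0.95,3.38,-0.66
D,wet,As,0.25,0.59,-2.60
D,wet,Cr,4.03,9.53,1.42
D,wet,Cu,1.22,2.88,-0.30
D,wet,Fe,0.43,1.00,-1.82
D,wet,Zn,1.18,2.77,-0.35
D,dry,As,0.27,0.56,-2.49
D,dry,Cr,4.62,9.46,1.62
D,dry,Cu,1.56,3.19,0.06
D,dry,Fe,0.49,1.00,-1.61
D,dry,Zn,1.50,3.07,-0.01
E,wet,As,0.34,0.83,-2.20
E,wet,Cr,3.89,9.43,1.37
E,wet,Cu,1.12,2.71,-0.43
E,wet,Fe,0.41,1.00,-1.86
E,wet,Zn,1.26,3.05,-0.25
E,dry,As,0.15,0.41,-3.34
E,dry,Cr,3.67,10.02,1.29
E,dry,Cu,1.29,3.53,-0.23
E,dry,Fe,0.37,1.00,-2.04
E,dry,Zn,1.20,3.27,-0.33
F,wet,As,0.25,0.96,-2.62
F,wet,Cr,3.15,12.15,1.07
F,wet,Cu,1.76,6.86,0.23
F,wet,Fe,0.26,1.00,-2.52
F,wet,Zn,1.23,4.73,-0.29
F,dry,As,0.16,0.57,-3.27
F,dry,Cr,2.27,8.01,0.59
F,dry,Cu,1.60,5.72,0.10
F,dry,Fe,0.29,1.00,-2.40
F,dry,Zn,0.86,3.09,-0.81
G,wet,As,0.11,0.41,-3.75
G,wet,Cr,4.69,17.38,1.64
G,wet,Cu,1.77,6.55,0.24
G,wet,Fe,0.28,1.00,-2.46
G,wet,Zn,0.66,2.46,-1.18
G,dry,As,0.11,0.48,-3.75
G,dry,Cr,4.36,18.49,1.54
G,dry,Cu,1.73,7.32,0.20
G,dry,Fe,0.24,1.00,-2.66
G,dry,Zn,0.53,2.20,-1.52
H,wet,As,0.30,1.38,-2.36
H,wet,Cr,2.87,13.17,0.92
H,wet,Cu,2.48,11.41,0.72
H,wet,Fe,0.22,1.00,-2.78
H,wet,Zn,0.57,2.61,-1.40
H,dry,As,0.12,0.62,-3.67
H,dry,Cr,2.57,13.44,0.77
H,dry,Cu,2.71,14.27,0.85
H,dry,Fe,0.19,1.00,-2.98
H,dry,Zn,0.71,3.72,-1.09
I,wet,As,,,
I,wet,Cr,2.44,13.98,0.70
I,wet,Cu,2.51,14.41,0.74
I,wet,Fe,0.18,1.00,-3.10
I,wet,Zn,0.48,2.79,-1.63
I,dry,As,,,
I,dry,Cr,2.77,11.07,0.88
I,dry,Cu,2.75,11.04,0.88
I,dry,Fe,0.26,1.00,-2.55
I,dry,Zn,0.60,2.43,-1.34
J,wet,As,,,
J,wet,Cr,2.41,8.91,0.68
J,wet,Cu,2.70,9.91,0.84
J,wet,Fe,0.28,1.00,-2.44
J,wet,Zn,0.75,2.70,-1.01
J,dry,As,,,
J,dry,Cr,2.89,9.11,0.93
J,dry,Cu,2.57,8.14,0.77
J,dry,Fe,0.32,1.00,-2.24
J,dry,Zn,0.71,2.33,-1.13
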