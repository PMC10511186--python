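label,area_mm2,definition,mcb_o_mm,mcb_5_mm,mcb_8_mm
A_1,8.1,kamp,0.48,0.51,0.52
A_2,4.9,kamp,0.54,0.57,0.59
A_3,27.6,kamp,0.53,0.55,0.57
A_4,4.8,kamp,0.39,0.41,0.42
I_B,7,kamp,0.60,0.63,0.64
I_C,22.4,kamp,0.59,0.62,0.63
I_D,12.4,kamp,0.57,0.60,0.61
I_E,6.4,kamp,0.44,0.47,0.48
I_F,7,kamp,0.39,0.41,0.42
I_G,8.9,kamp,0.38,0.40,0.41
I_H,7.7,kamp,0.44,0.47,0.48
H_A,10.4,kamp,0.59,0.62,0.64
H_B,15.7,kamp,0.66,0.69,0.71
H_C,15,kamp,0.65,0.69,0.70
H_D,9.2,kamp,0.62,0.65,0.67
H_E,10,kamp,0.47,0.49,0.51
T_1,42.7,kamp,0.66,0.69,0.71
T_2,42.5,kamp,1.32,1.38,1.42
T_3,23.4,kamp,0.75,0.79,0.81
A_1,8.1,penrose,0.53,0.56,0.58
A_2,4.9,penrose,0.58,0.61,0.62
A_3,27.6,penrose,0.58,0.61,0.62
A_4,4.8,penrose,0.40,0.42,0.43
I_B,7,penrose,0.54,0.57,0.59
I_C,22.4,penrose,0.64,0.67,0.69
I_D,12.4,penrose,0.49,0.52,0.53
I_E,6.4,penrose,0.44,0.46,0.47
I_F,7,penrose,0.54,0.57,0.58
I_G,8.9,penrose,0.51,0.54,0.55
I_H,7.7,penrose,0.50,0.53,0.54
H_A,10.4,penrose,0.78,0.82,0.84
H_B,15.7,penrose,0.71,0.75,0.77
H_C,15,penrose,0.72,0.76,0.78
H_D,9.2,penrose,0.60,0.63,0.65
H_E,10,penrose,0.56,0.59,0.61
T_1,42.7,penrose,0.83,0.88,0.90
T_2,42.5,penrose,1.29,1.36,1.40
T_3,23.4,penrose,0.74,0.78,0.80
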