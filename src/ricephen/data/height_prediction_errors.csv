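species,height_m,rmse_normal,rmse_low,mae_normal,mae_low,n_normal,n_low
N_lugens,2.00,4.55,6.40,3.75,5.95,10,9
N_lugens,1.00,3.84,4.71,3.38,4.31,10,9
N_lugens,0.75,3.25,4.00,2.82,3.57,10,9
N_lugens,0.50,3.10,3.33,2.61,2.88,10,9
N_lugens,0.25,3.12,2.81,2.78,2.43,10,9
N_lugens,0.00,4.02,3.05,3.77,2.81,10,9
S_furcifera,2.00,5.11,5.57,4.69,4.75,12,10
S_furcifera,1.00,4.42,4.96,3.67,4.19,12,10
S_furcifera,0.75,3.98,4.55,3.31,3.99,12,10
S_furcifera,0.50,3.88,4.15,3.22,3.72,12,10
S_furcifera,0.25,3.88,3.82,3.23,3.49,12,10
S_furcifera,0.00,4.49,3.23,3.70,2.91,12,10
L_striatellus,2.00,4.57,4.09,3.81,3.24,9,8
L_striatellus,1.00,3.78,3.52,3.26,2.71,9,8
L_striatellus,0.75,3.65,3.22,3.15,2.59,9,8
L_striatellus,0.50,3.61,2.90,2.99,2.31,9,8
L_striatellus,0.25,3.64,2.89,3.03,2.28,9,8
L_striatellus,0.00,4.19,4.04,3.22,3.20,9,8
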