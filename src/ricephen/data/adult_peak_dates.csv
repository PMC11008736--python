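species,transplant,plot,event_index,date
N_lugens,May,normal,0,2021-07-30
N_lugens,May,normal,1,2021-08-27
N_lugens,May,normal,2,2021-09-28
N_lugens,May,normal,0,2021-08-14
N_lugens,May,normal,1,2021-09-07
N_lugens,May,normal,2,2021-10-05
N_lugens,May,low,0,2021-07-30
N_lugens,May,low,1,2021-08-27
N_lugens,May,low,0,2021-08-14
N_lugens,May,low,1,2021-09-14
N_lugens,June,normal,0,2021-07-30
N_lugens,June,normal,1,2021-08-27
N_lugens,June,normal,0,2021-08-14
N_lugens,June,normal,1,2021-09-14
N_lugens,June,low,0,2021-07-30
N_lugens,June,low,1,2021-08-31
N_lugens,June,low,2,2021-10-05
N_lugens,June,low,0,2021-08-14
N_lugens,June,low,1,2021-09-14
N_lugens,July,normal,0,2021-07-30
N_lugens,July,normal,1,2021-08-24
N_lugens,July,normal,2,2021-09-21
N_lugens,July,normal,0,2021-08-14
N_lugens,July,normal,1,2021-09-14
N_lugens,July,normal,2,2021-10-19
N_lugens,July,low,0,2021-07-30
N_lugens,July,low,1,2021-08-27
N_lugens,July,low,0,2021-08-14
N_lugens,July,low,1,2021-09-10
N_lugens,July,low,2,2021-10-15
N_lugens,July,low,0,2021-09-03
N_lugens,July,low,1,2021-10-09
S_furcifera,May,normal,0,2021-07-09
S_furcifera,May,normal,1,2021-08-06
S_furcifera,May,normal,2,2021-08-31
S_furcifera,May,normal,0,2021-08-14
S_furcifera,May,normal,1,2021-09-10
S_furcifera,May,low,0,2021-06-09
S_furcifera,May,low,1,2021-07-06
S_furcifera,May,low,2,2021-08-03
S_furcifera,May,low,0,2021-08-14
S_furcifera,May,low,1,2021-09-07
S_furcifera,June,normal,0,2021-07-09
S_furcifera,June,normal,1,2021-08-03
S_furcifera,June,normal,2,2021-09-03
S_furcifera,June,normal,3,2021-10-01
S_furcifera,June,normal,0,2021-08-14
S_furcifera,June,normal,1,2021-09-10
S_furcifera,June,normal,2,2021-10-09
S_furcifera,June,low,0,2021-07-09
S_furcifera,June,low,1,2021-08-03
S_furcifera,June,low,2,2021-09-03
S_furcifera,June,low,0,2021-08-20
S_furcifera,June,low,1,2021-09-17
S_furcifera,July,normal,0,2021-08-03
S_furcifera,July,normal,1,2021-08-31
S_furcifera,July,normal,2,2021-09-28
S_furcifera,July,normal,0,2021-08-14
S_furcifera,July,normal,1,2021-09-14
S_furcifera,July,normal,2,2021-10-12
S_furcifera,July,low,0,2021-08-03
S_furcifera,July,low,1,2021-09-03
S_furcifera,July,low,2,2021-09-28
S_furcifera,July,low,0,2021-08-14
S_furcifera,July,low,1,2021-09-14
S_furcifera,July,low,2,2021-10-12
L_striatellus,May,normal,0,2021-06-18
L_striatellus,May,normal,1,2021-07-13
L_striatellus,May,normal,2,2021-08-06
L_striatellus,May,normal,3,2021-08-27
L_striatellus,May,normal,0,2021-08-13
L_striatellus,May,normal,1,2021-09-10
L_striatellus,May,low,0,2021-06-25
L_striatellus,May,low,1,2021-07-20
L_striatellus,May,low,0,2021-08-13
L_striatellus,May,low,1,2021-09-10
L_striatellus,June,normal,0,2021-07-09
L_striatellus,June,normal,1,2021-08-06
L_striatellus,June,normal,2,2021-09-07
L_striatellus,June,normal,3,2021-10-15
L_striatellus,June,low,0,2021-07-09
L_striatellus,June,low,1,2021-08-06
L_striatellus,June,low,2,2021-09-10
L_striatellus,June,low,0,2021-07-20
L_striatellus,June,low,1,2021-08-17
L_striatellus,June,low,2,2021-09-17
L_striatellus,July,normal,0,2021-08-03
L_striatellus,July,normal,1,2021-08-31
L_striatellus,July,normal,0,2021-08-17
L_striatellus,July,normal,1,2021-09-17
L_striatellus,July,low,0,2021-08-03
L_striatellus,July,low,1,2021-08-31
L_striatellus,July,low,0,2021-08-20
L_striatellus,July,low,1,2021-09-14
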