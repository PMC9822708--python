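vowel,pitch,quality,op_hp_ratio,L_cm
aa,Ab4,Belting,7.6,11.48
aa,Ab4,Twang,6.8,12.21
aa,Ab4,Opera,1.4,16.58
aa,Ab4,Sobbing,1.2,15.31
aa,Ab4,Speech,4.4,11.98
aa,Ab4,Falsetto,2.6,12.68
ii,Ab4,Belting,1.3,13.74
ii,Ab4,Twang,1.4,13.41
ii,Ab4,Opera,1.0,15.65
ii,Ab4,Sobbing,0.5,14.8
ii,Ab4,Speech,0.8,13.31
ii,Ab4,Falsetto,0.6,13.96
aa,Ab3,Belting,4.9,11.5
aa,Ab3,Twang,2.5,12.68
aa,Ab3,Opera,1.4,15.69
aa,Ab3,Sobbing,0.6,16.7
aa,Ab3,Speech,3.0,12.88
aa,Ab3,Falsetto,1.4,14.14
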