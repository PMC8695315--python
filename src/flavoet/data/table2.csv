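protein,donor,subunit,b3,c3,xm_rc_printed,xm_es_printed,xm_esrc_printed,known_mismatch,annotation
FBP,Trp32,A,-1,1.73,0.82,0.77,0.91,0,the one donor whose X_m(ESRc) and X_m(ES) disagree beyond tolerance (0.91 vs 0.77)
FBP,Trp32,B,-1.66,2.16,0.82,0.82,0.80,0,
FBP,Trp106,A,-0.66,1.52,0.90,0.90,0.92,1,B3*X_m(Rc)+C3 = 0.926 -> 0.93; printed 0.92 is one display ulp low
FBP,Trp106,B,-0.82,1.64,0.94,0.94,0.87,0,ESRC fitted over the short-distance conformation only (Rc < 1.15 nm)
WT P2O,Trp168,B,-0.58,2.3,0.74,1.86,1.87,0,
WT P2O,Trp168,C,-0.6,2.3,0.73,1.87,1.86,0,
WT P2O,Trp168,D,-0.44,2.17,0.73,1.86,1.85,0,
T169S P2O,Trp168,A,-0.48,2.44,0.71,2.10,2.10,0,
T169S P2O,Trp168,B,-0.51,2.48,0.73,2.11,2.11,0,
T169S P2O,Trp168,D,-0.39,2.4,0.72,2.13,2.12,0,
MCAD,Trp166,A,-0.32,2.71,0.76,2.40,2.47,0,
MCAD,Trp166,B,-0.45,2.83,0.81,2.37,2.46,1,B3*X_m(Rc)+C3 = 2.4655 -> 2.47; printed 2.46 is one display ulp low
MCAD,Trp166,C,-0.34,2.62,0.74,2.30,2.37,0,
MCAD,Trp166,D,-0.38,2.75,0.80,2.37,2.45,0,
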