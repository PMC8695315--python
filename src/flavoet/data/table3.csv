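protein,donor,subunit,wavelength_nm,a4,b4,c4,xm_es_printed,b5,c5,xm_rc_printed,b6,c6,known_mismatch,annotation
WT P2O,Trp168,B,580,-21.4,72.2,-58.2,1.69,-4.61,5.87,0.54,-0.581,2.00,0,
WT P2O,Trp168,C,580,-16.9,57.6,-46.3,1.70,-5.11,6.22,0.51,-0.6,2.01,0,
WT P2O,Trp168,D,580,-22.5,75.5,-50.7,1.68,-4.61,5.81,0.46,-0.441,1.88,0,
T169S P2O,Trp168,A,580,-10.8,42.3,-39.1,1.96,-6.78,6.34,0.07,-0.476,1.99,0,
T169S P2O,Trp168,B,580,-15.7,61.3,-57,1.95,-6.61,6.3,0.15,-0.508,2.03,0,running text gives B4=63.1 vs table 61.3; only 61.3 reproduces the printed peak (table canonical)
T169S P2O,Trp168,D,580,-25.8,94.9,-85.1,1.84,-6.15,5.98,0.29,-0.388,1.95,0,
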