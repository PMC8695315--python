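protein,donor,subunit,a2,b2,c2,xm_es_printed,neg_sfeg_range,known_mismatch,annotation
FBP,Trp32,A,-26.1,40.3,-13.4,0.77,0.87-1.15,0,printed X_m(ES) 0.77 lies outside the printed -SFEG range despite the running-text claim that all peaks fall inside their ranges
FBP,Trp32,B,-27.1,40,-12.7,0.82,0.78-1.15,1,-B2/(2A2)=0.74; printed 0.82 coincides with the quoted X_m(Rc) for this donor (likely column transcription)
FBP,Trp106,A,-28,47.7,-18,0.90,0.72-1.10,1,-B2/(2A2)=0.85; printed 0.90 coincides with the quoted X_m(Rc) for this donor (likely column transcription)
FBP,Trp106,B,-114,193,-80,0.94,0.5-0.95,1,-B2/(2A2)=0.85; printed 0.94 coincides with the quoted X_m(Rc); running text gives B2=194 vs table 193 (table canonical)
WT P2O,Trp168,B,-15.3,56.8,-50,1.86,1.81-1.92,0,running text gives A2=-15.8 vs table -15.3; only -15.3 reproduces the printed peak (table canonical)
WT P2O,Trp168,C,-13.4,50,-43.8,1.87,1.79-1.91,0,
WT P2O,Trp168,D,-18.3,68.2,-60.5,1.86,1.79-1.89,0,
T169S P2O,Trp168,A,-13.4,56.4,-57,2.10,1.62-1.71,0,
T169S P2O,Trp168,B,-24.4,103,-1.7,2.11,1.62-1.71,0,
T169S P2O,Trp168,D,-22.4,95.4,-98.8,2.13,1.61-1.71,0,
MCAD,Trp166,A,-19.3,92.5,-110,2.40,2.33-2.54,0,
MCAD,Trp166,B,-9.28,43.9,-50.4,2.37,2.3-2.58,0,running text garbles this row (quotes 49.3); table value 43.9 reproduces the printed peak (table canonical)
MCAD,Trp166,C,-9.65,44.3,-49.1,2.30,2.25-2.41,0,
MCAD,Trp166,D,-9.5,45,-51.9,2.37,2.33-2.54,0,
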