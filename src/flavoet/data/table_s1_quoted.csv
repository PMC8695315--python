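protein,donor,subunit,xm_rc,rc_range,source_note
FBP,Trp32,A,0.82,0.64-0.80,distance-law peak and Rc range quoted in the main text; X_m(Rc) beyond the range: entirely distance-inverted
FBP,Trp32,B,0.82,0.62-0.78,distance-law peak and Rc range quoted in the main text; X_m(Rc) beyond the range: entirely distance-inverted
FBP,Trp106,A,0.90,0.82-1.10,distance-law peak and Rc range quoted in the main text
FBP,Trp106,B,0.94,0.82-1.82,distance-law peak and Rc range quoted in the main text; two conformations (short/long Rc)
WT P2O,Trp168,B,0.74,0.66-0.82,distance-law peak and Rc range quoted in the main text
WT P2O,Trp168,C,0.73,0.71-0.82,distance-law peak and Rc range quoted in the main text
WT P2O,Trp168,D,0.73,0.69-0.83,distance-law peak and Rc range quoted in the main text
T169S P2O,Trp168,A,0.71,0.68-0.79,distance-law peak and Rc range quoted in the main text
T169S P2O,Trp168,B,0.73,,distance-law peak quoted in the main text; no Rc range quoted for this subunit
T169S P2O,Trp168,D,0.72,0.68-0.84,distance-law peak and Rc range quoted in the main text
MCAD,Trp166,A,0.76,0.77-1.0,distance-law peak and Rc range quoted in the main text
MCAD,Trp166,B,0.81,0.72-0.97,distance-law peak and Rc range quoted in the main text
MCAD,Trp166,C,0.74,0.75-0.95,distance-law peak and Rc range quoted in the main text
MCAD,Trp166,D,0.80,0.75-1.0,distance-law peak and Rc range quoted in the main text
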