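compound,condition,mean_rcy_pct,sd_rcy_pct
DOTAMTATE,10 min at RT,96.5,0.7
PSC-TATE,10 min at RT,73.2,6.0
PSC-PEG2-TATE,10 min at RT,72.1,4.7
DOTATATE,10 min at RT,94.3,0.7
PSC-TATE,20 additional min at RT,93.3,2.4
PSC-PEG2-TATE,20 additional min at RT,89.9,1.6
DOTATATE,20 additional min at RT,99.2,0.3
PSC-TATE,20 additional min at 37C,99.3,0.3
PSC-PEG2-TATE,20 additional min at 37C,99.3,0.1
DOTAMTATE,24 h at RT,99.0,0.0
PSC-TATE,24 h at RT,98.7,0.6
PSC-PEG2-TATE,24 h at RT,98.7,0.6
DOTATATE,24 h at RT,98.3,1.2
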