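compound,tpsa,mw,clogp,hba,hbd,rb
4a,57.97,258,2.28,3,0,2
4b,57.97,272,2.62,3,0,2
4c,57.97,337,3.00,3,0,2
4d,57.97,276,2.38,3,0,2
4e,67.20,288,2.21,4,0,3
4f,67.20,288,2.21,4,0,3
4g,57.97,327,3.49,3,0,2
4h,86.21,264,2.15,3,0,2
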