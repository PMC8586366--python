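target,temperature_C,ksv,log_kb,kb,n,delta_g_kcal
BSA,25,4.2e4,5.2,1.8e5,1.1,-7.06
BSA,30,4.1e4,4.5,3.3e4,0.9,-6.21
BSA,35,3.4e4,4.3,2.2e4,0.9,-5.94
DNA,25,1.2e4,3.6,3.9e3,0.8,-4.8
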