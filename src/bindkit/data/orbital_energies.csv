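compound,e_homo_ev,e_lumo_ev
4a,-6.314,-3.809
4b,-6.304,-3.589
4c,-6.284,-3.257
4d,-6.281,-3.059
4e,-6.276,-3.440
4f,-6.288,-3.225
4g,-6.261,-2.716
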