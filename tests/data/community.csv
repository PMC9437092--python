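community,sp01,sp02,sp03,sp04,sp05,sp06,sp07,sp08,sp09,sp10,sp11,sp12
site1,73.0,51.0,36.0,25.0,18.0,12.0,9.0,6.0,4.0,3.0,2.0,1.0
site2,20.0,20.0,20.0,20.0,20.0,20.0,20.0,20.0,20.0,20.0,20.0,20.0
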