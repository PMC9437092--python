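cont1: continuous
cont2: continuous
nom1: nominal
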