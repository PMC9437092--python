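species,cont1,cont2,nom1
sp01,0.17075914255172034,0.5003666089287064,c1
sp02,0.14461428837245757,0.9402846804181118,c2
sp03,0.18604741441083672,0.9388692355431394,c2
sp04,0.10872816071096618,0.5458916580304843,c0
sp05,0.0902679296495737,0.4329693344360782,c0
sp06,0.6249606368752767,0.0011863235591651209,c1
sp07,0.06839124659777063,0.901843383229831,c2
sp08,0.5588497679966399,-0.050950813092815045,c1
sp09,0.5169509694648726,0.039729844592932766,c1
sp10,0.1608601611948519,0.4966629110450938,c0
sp11,0.5383083334544225,0.021422920152195334,c1
sp12,0.1856843932651301,0.9184159445667612,c2
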