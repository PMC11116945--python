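genus_id,trophic_group
Genus01,FF
Genus02,OP
Genus03,BF
Genus04,BF
Genus05,BF
Genus06,OP
Genus07,BF
Genus08,PF
Genus09,FF
Genus10,PF
Genus11,PF
Genus12,OP
Genus13,PF
Genus14,FF
Genus15,PF
Genus16,BF
Genus17,FF
Genus18,PF
Genus19,BF
Genus20,BF
Genus21,BF
Genus22,BF
Genus23,BF
Genus24,BF
Genus25,PF
Genus26,PF
Genus27,FF
Genus28,PF
Genus29,OP
Genus30,BF
Genus31,PF
Genus32,OP
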