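# Mammalian cortical area development network (Giacomantonio & Goodhill 2010).
# Five transcription/signalling factors patterning the anterior-posterior axis
# of the developing cortex. Synchronous update yields two fixed-point
# attractors: the anterior phenotype (Fgf8/Pax6/Sp8 on) and the posterior
# phenotype (Emx2/Coup_tfi on).
targets, factors
Fgf8, Fgf8 & Sp8 & !Emx2
Emx2, Coup_tfi & !Fgf8 & !Pax6 & !Sp8
Pax6, Sp8 & !Emx2 & !Coup_tfi
Sp8, Fgf8 & !Emx2
Coup_tfi, !Fgf8 & !Sp8
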