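ligand	receptor
Apoe	Lrp1
Apoe	Ldlr
Bdnf	Ntrk2
Ngf	Ntrk1
Tgfb1	Tgfbr1
Tgfb1	Tgfbr2
Il1b	Il1r1
Il6	Il6ra
Tnf	Tnfrsf1a
Tnf	Tnfrsf1b
Cx3cl1	Cx3cr1
Ccl2	Ccr2
Ccl5	Ccr5
Csf1	Csf1r
Vegfa	Flt1
Vegfa	Kdr
Pdgfb	Pdgfrb
Edn1	Ednrb
Efnb2	Ephb4
Dll1	Notch1
Jag1	Notch2
Wnt3a	Fzd1
Shh	Ptch1
Igf1	Igf1r
Fgf2	Fgfr1
Gas6	Axl
Psap	Gpr37
Nrg1	Erbb4
Sema4d	Plxnb1
Ptn	Ptprz1
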