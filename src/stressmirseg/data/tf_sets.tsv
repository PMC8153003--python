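miRNA	regulator
miR-15a-5p	Batf
miR-15a-5p	Bcl11b
miR-15a-5p	Brd4
miR-15a-5p	Btaf1
miR-15a-5p	Cbfb
miR-15a-5p	Cebpa
miR-15a-5p	Cebpb
miR-15a-5p	Ctcf
miR-15a-5p	DECOY_TF_miR-15a-5p_1
miR-15a-5p	DECOY_TF_miR-15a-5p_2
miR-15a-5p	DECOY_TF_miR-15a-5p_3
miR-15a-5p	Ep300
miR-15a-5p	Erg
miR-15a-5p	Ets1
miR-15a-5p	Hdac2
miR-15a-5p	Ikzf1
miR-15a-5p	Mafb
miR-15a-5p	Max
miR-15a-5p	Med1
miR-15a-5p	Myc
miR-15a-5p	Nelfe
miR-15a-5p	Nr1d1
miR-15a-5p	Nr3c1
miR-15a-5p	Otx2
miR-15a-5p	Pou5f1
miR-15a-5p	Pparg
miR-15a-5p	Rad21
miR-15a-5p	Rela
miR-15a-5p	Smarca4
miR-15a-5p	Spi1
miR-15a-5p	Suz12
miR-15a-5p	Tcf12
miR-15a-5p	Tfap4
miR-15a-5p	Zfp281
miR-15a-5p	Zfp384
let-7d-5p	Cebpa
let-7d-5p	DECOY_TF_let-7d-5p_1
let-7d-5p	DECOY_TF_let-7d-5p_2
let-7d-5p	DECOY_TF_let-7d-5p_3
let-7d-5p	Spi1
miR-511-5p	Batf
miR-511-5p	Btaf1
miR-511-5p	Cebpa
miR-511-5p	Cebpb
miR-511-5p	DECOY_TF_miR-511-5p_1
miR-511-5p	DECOY_TF_miR-511-5p_2
miR-511-5p	DECOY_TF_miR-511-5p_3
miR-511-5p	Fli1
miR-511-5p	Mafb
miR-511-5p	Nr3c1
miR-511-5p	Rela
miR-511-5p	Spi1
miR-511-5p	Stat5a
miR-511-5p	Tcf12
miR-497a-5p	Bcl11b
miR-497a-5p	Brd4
miR-497a-5p	Cbfb
miR-497a-5p	Cebpb
miR-497a-5p	Ctcf
miR-497a-5p	DECOY_TF_miR-497a-5p_1
miR-497a-5p	DECOY_TF_miR-497a-5p_2
miR-497a-5p	DECOY_TF_miR-497a-5p_3
miR-497a-5p	Ep300
miR-497a-5p	Erg
miR-497a-5p	Ets1
miR-497a-5p	Fli1
miR-497a-5p	Hdac2
miR-497a-5p	Ikzf1
miR-497a-5p	Max
miR-497a-5p	Med1
miR-497a-5p	Myc
miR-497a-5p	Nelfe
miR-497a-5p	Nr1d1
miR-497a-5p	Nr3c1
miR-497a-5p	Otx2
miR-497a-5p	Pou5f1
miR-497a-5p	Pparg
miR-497a-5p	Rad21
miR-497a-5p	Rela
miR-497a-5p	Smarca4
miR-497a-5p	Spi1
miR-497a-5p	Stat5a
miR-497a-5p	Suz12
miR-497a-5p	Tfap4
miR-497a-5p	Zfp281
miR-497a-5p	Zfp384
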