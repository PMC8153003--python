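miRNA	regulator
miR-15a-5p	DECOY_LNC_miR-15a-5p_1
miR-15a-5p	DECOY_LNC_miR-15a-5p_2
miR-15a-5p	DECOY_LNC_miR-15a-5p_3
miR-15a-5p	ENSMUSG00000085287
miR-15a-5p	ENSMUSG00000093535
miR-15a-5p	Gm11579
miR-15a-5p	Gm20605
miR-15a-5p	Gm4117
miR-15a-5p	Kcnq1ot1
miR-15a-5p	Ptprv
miR-15a-5p	Rab10os
let-7d-5p	DECOY_LNC_let-7d-5p_1
let-7d-5p	DECOY_LNC_let-7d-5p_2
let-7d-5p	DECOY_LNC_let-7d-5p_3
let-7d-5p	Gm20605
let-7d-5p	Gm26856
let-7d-5p	Gm4117
let-7d-5p	Kcnq1ot1
let-7d-5p	Mecomos
let-7d-5p	Ptprv
let-7d-5p	Zfp950
miR-511-5p	DECOY_LNC_miR-511-5p_1
miR-511-5p	DECOY_LNC_miR-511-5p_2
miR-511-5p	DECOY_LNC_miR-511-5p_3
miR-511-5p	ENSMUSG00000085287
miR-511-5p	ENSMUSG00000093535
miR-511-5p	Gm11579
miR-511-5p	Gm26856
miR-511-5p	Gm4117
miR-511-5p	Kcnq1ot1
miR-511-5p	Rab10os
miR-511-5p	Zfp950
miR-497a-5p	DECOY_LNC_miR-497a-5p_1
miR-497a-5p	DECOY_LNC_miR-497a-5p_2
miR-497a-5p	DECOY_LNC_miR-497a-5p_3
miR-497a-5p	ENSMUSG00000093535
miR-497a-5p	Gm11579
miR-497a-5p	Gm20605
miR-497a-5p	Gm4117
miR-497a-5p	Kcnq1ot1
miR-497a-5p	Mecomos
miR-497a-5p	Ptprv
miR-497a-5p	Rab10os
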