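sample	genus	species_group	data_type
A_fraterculus_SP1	Anastrepha	fraterculus	transcriptome
A_fraterculus_ES	Anastrepha	fraterculus	transcriptome
A_fraterculus_RJ	Anastrepha	fraterculus	transcriptome
A_fraterculus_RS1	Anastrepha	fraterculus	transcriptome
A_fraterculus_AR	Anastrepha	fraterculus	transcriptome
A_fraterculus_SC	Anastrepha	fraterculus	transcriptome
A_fraterculus_SP2	Anastrepha	fraterculus	transcriptome
A_fraterculus_BA	Anastrepha	fraterculus	transcriptome
A_fraterculus_SP3	Anastrepha	fraterculus	transcriptome
A_fraterculus_RS2	Anastrepha	fraterculus	wgrs
A_fraterculus_MX	Anastrepha	fraterculus	wgrs
A_fraterculus_CUS	Anastrepha	fraterculus	wgrs
A_fraterculus_LOR	Anastrepha	fraterculus	wgrs
A_fraterculus_ANC	Anastrepha	fraterculus	wgrs
A_fraterculus_MDD	Anastrepha	fraterculus	wgrs
A_fraterculus_CO	Anastrepha	fraterculus	wgrs
A_fraterculus_EC	Anastrepha	fraterculus	wgrs
A_turpiniae_MG	Anastrepha	fraterculus	transcriptome
A_turpiniae_SP	Anastrepha	fraterculus	transcriptome
A_distincta_SP	Anastrepha	fraterculus	transcriptome
A_obliqua_RJ	Anastrepha	fraterculus	transcriptome
A_obliqua_GO	Anastrepha	fraterculus	transcriptome
A_obliqua_PR1	Anastrepha	fraterculus	transcriptome
A_obliqua_PR2	Anastrepha	fraterculus	transcriptome
A_obliqua_CO	Anastrepha	fraterculus	genome
A_suspensa_US	Anastrepha	fraterculus	genome
A_ludens_US	Anastrepha	fraterculus	genome
A_psidivora	Anastrepha	incertae_sedis	wgrs
A_bistrigata	Anastrepha	striata	transcriptome
A_striata	Anastrepha	striata	wgrs
A_pseudoparallela	Anastrepha	pseudoparallela	transcriptome
A_grandis	Anastrepha	grandis	transcriptome
A_serpentina	Anastrepha	serpentina	transcriptome
A_hadracantha	Anastrepha	mucronata	wgrs
A_leptozona	Anastrepha	leptozona	wgrs
A_curitis	Anastrepha	leptozona	wgrs
R_zephyria	Rhagoletis	outgroup	genome
C_capitata	Ceratitis	outgroup	genome
Z_cucurbitae	Zeugodacus	outgroup	genome
B_dorsalis	Bactrocera	outgroup	genome
B_oleae	Bactrocera	outgroup	genome
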