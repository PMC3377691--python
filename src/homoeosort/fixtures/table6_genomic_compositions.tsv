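section	species	ploidy	components
Virgata	P. amarum	6x, 8x	AB
Virgata	P. amarulum	4x	AB
Virgata	P. virgatum	4x, 8x	AB
Virgata	P. virgatum subsp. cubense	4x	AB
Virgata	P. tricholaenoides	4x	AB
Urvilleana	P. chloroleucum	4x, 6x?	AB
Urvilleana	P. racemosum	4x, 6x?	AB(+)
Urvilleana	P. urvilleanum	4x	AB
Incertae sedis	P. mystasipum	6x	CDE
Incertae sedis	P. olyroides	4x	CD
Dichotomiflora	P. aquaticum	8x	IJKL
Dichotomiflora	P. dichotomiflorum	4x	IL
Dichotomiflora	P. elephantipes	6x	KL(+)
Dichotomiflora	P. gouinii	4x	JK
Dichotomiflora	P. pedersenii	8x	IJKL
Dichotomiflora	P. aff. aquaticum	6x, 8x?	IJKL
Panicum	P. bergii	4x	FG
Panicum	P. capillare	2x	F
Panicum	P. miliaceum	4x	FH
Panicum	P. nephelophilum	2x	F
Panicum	P. stramineum	4x	FG
Rudgeana	P. rudgei	2x	E
Rudgeana	P. cervicatum	2x	E
Rudgeana	P. campestre	2x	E
Rudgeana	P. cayennense	2x	E
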