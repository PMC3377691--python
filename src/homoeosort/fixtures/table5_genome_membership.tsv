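genome	sections	species
A	Urvilleana;Virgata	P. amarum;P. amarulum;P. chloroleucum;P. racemosum;P. tricholaenoides;P. urvilleanum;P. virgatum
B	Urvilleana;Virgata	P. amarum;P. amarulum;P. chloroleucum;P. racemosum;P. tricholaenoides;P. urvilleanum;P. virgatum
C	Incertae sedis	P. mystasipum;P. olyroides
D	Incertae sedis	P. mystasipum;P. olyroides
E	Rudgeana;Incertae sedis	P. cayennense;P. cervicatum;P. campestre;P. rudgei;P. mystasipum
F	Panicum	P. bergii;P. capillare;P. miliaceum;P. nephelophilum;P. stramineum
G	Panicum	P. bergii;P. stramineum
H	Panicum	P. miliaceum
I	Dichotomiflora	P. aquaticum;P. dichotomiflora;P. pedersenii
J	Dichotomiflora	P. aquaticum;P. gouinii;P. pedersenii
K	Dichotomiflora	P. aquaticum;P. elephantipes;P. gouinii;P. pedersenii
L	Dichotomiflora	P. aquaticum;P. dichotomiflora;P. elephantipes;P. pedersenii
kl	Dichotomiflora	P. elephantipes
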