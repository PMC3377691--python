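taxon	accession	ploidy_estimate	n_samples
P. amarulum	aml419	4x	2
P. amarulum	aml421901	4x	1
P. amarulum	aml476814-1	4x	1
P. amarulum	aml476815-1	4x	1
P. amarulum	aml476815-2	4x	1
P. amarum	ama7	8x	2
P. amarum	ama8	6x	1
P. amarum	ama9	6x	1
P. amarum	ama10	6x	1
P. amarum	ama11	6x	1
P. amarum	ama12	6x	1
P. amarum	ama561721	6x	1
P. amarum	ama645599	6x	1
P. virgatum (lowland ecotype)	vir441	4x	1
P. virgatum (lowland ecotype)	vir315723	4x	1
P. virgatum (lowland ecotype)	vir414065	4x	1
P. virgatum (lowland ecotype)	vir414070	4x	1
P. virgatum (lowland ecotype)	vir421521	4x	1
P. virgatum (lowland ecotype)	vir421999	4x	1
P. virgatum (lowland ecotype)	vir422006	4x	1
P. virgatum (lowland ecotype)	vir422016	4x	1
P. virgatum (lowland ecotype)	vir476291	4x	2
P. virgatum (lowland ecotype)	vir607837	4x	1
P. virgatum subsp. cubense	cub315728	4x	2
P. virgatum (upland ecotype)	vir16409	8x	1
P. virgatum (upland ecotype)	vir315724	8x	1
P. virgatum (upland ecotype)	vir315725	4x	1
P. virgatum (upland ecotype)	vir337553	8x	1
P. virgatum (upland ecotype)	vir414066	8x	1
P. virgatum (upland ecotype)	vir414067	8x	1
P. virgatum (upland ecotype)	vir414069	8x	1
P. virgatum (upland ecotype)	vir421138	8x	1
P. virgatum (upland ecotype)	vir421520	8x	1
P. virgatum (upland ecotype)	vir431575	8x	1
P. virgatum (upland ecotype)	vir469228	8x	1
P. virgatum (upland ecotype)	vir476292	8x	1
P. virgatum (upland ecotype)	vir476293	4x	1
P. virgatum (upland ecotype)	vir476296	4x	1
P. virgatum (upland ecotype)	vir476297	8x	1
P. virgatum (upland ecotype)	vir549094	8x	1
P. aff. aquaticum	unkCR3	6x	1
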