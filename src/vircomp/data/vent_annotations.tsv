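gene_id	sample_id	fraction	ec	ko	category	pathway_ids
mic001	vent	microbiome	1.8.1.9		F	P1
mic002	vent	microbiome	1.17.4.1		F	P1
mic003	vent	microbiome	6.3.4.4		E	P2
mic004	vent	microbiome	4.3.2.2		E	P2
mic005	vent	microbiome	6.3.4.5		E	P2
mic006	vent	microbiome	4.3.2.1		E	P2
mic007	vent	microbiome		FrdA	C	P3
mic008	vent	microbiome		FrdB	C	P3
mic009	vent	microbiome		FrdC	C	P3
mic010	vent	microbiome		FrdD	C	P3
mic011	vent	microbiome		NarX	T	P3
mic012	vent	microbiome		NarL	T	P3
mic013	vent	microbiome	2.6.1.102		G	P6
mic014	vent	microbiome	2.1.2.13		G	P6
mic015	vent	microbiome	2.4.2.53		G	P6
vir001	vent	virome	1.17.4.2		F	P1
vir002	vent	virome	4.3.1.1		E	P2
vir003	vent	virome		NarG	C	P3
vir004	vent	virome		NarH	C	P3
vir005	vent	virome		NarJ	C	P3
vir006	vent	virome		NarI	C	P3
vir007	vent	virome		UhpC	T	P3
vir008	vent	virome		CTH	E	P4
vir009	vent	virome	2.9.1.1		J	P4;P5
vir010	vent	virome	1.1.1.281		G	P6
vir011	vent	virome	2.6.1.87		G	P6
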