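lineage	localities	described_species	nuclear_data	mtdna_monophyly	adora3	eno	fga	vwf	profile	gsi_significant	flags
M. griseorufus	Griseorufus	1	1	1.0	0	0.99	0	0.0004	1:0.28,2:0.71	1	none
M. murinus sensu lato	Bemanasy;Andranomena;Kirindy;Mamamby;Vohimena;Mandena	1	1	1.0	0	0.04	0	0	3:0.17,4:0.29,5:0.28,6:0.25	0	none
M. murinus Bemanasy	Bemanasy	0	1	1.0	0	0	0	0	3:0.99,4:0.01	1	none
M. murinus And/Kir/Manam/Vohi	Andranomena;Kirindy;Mamamby;Vohimena	0	1	0.0	0	0	0	0	3:0.05,4:0.47,5:0.45,6:0.03	1	composite-mtDNA-clades
M. murinus Mandena	Mandena	0	1	1.0	0	0	0	0	6:1.0	1	none
M. danfossi	Danfossi	1	0	1.0	NA	NA	NA	NA	NA	0	none
M. bongolavensis	Bongolavensis	1	0	0.99	NA	NA	NA	NA	NA	0	none
M. ravelobensis	Ravelobensis	1	1	1.0	0.9781	1.0	1.0	0.9914	7:1.0	1	none
Microcebus sp. Marolambo	Marolambo	0	1	1.0	0	1.0	0.576	0.205	8:1.0	1	none
Microcebus sp. Ivorona/Manantantely	Ivorona;Manantantely	0	1	1.0	0	0	0.9754	0	1:0.01,8:0.01,9:0.93,14:0.04,15:0.01	1	none
M. jollyae	Jollyae	1	0	0.0	NA	NA	NA	NA	NA	0	none
M. simmonsi	Simmonsi	1	1	1.0	0.9957	1.0	1.0	0.9914	10:1.0	1	none
M. tavaratra	Tavaratra	1	1	1.0	0.9318	1.0	0	0.16	11:0.99,19:0.01	1	none
M. mamiratra	NosyBe	1	1	1.0	0.001	0	0	0	12:1.0	0	none
Microcebus sp. Ambanja/Montagne d'Ambre	Ambanja;MontagneDambre	0	1	1.0	0	0.301	0	0	13:1.0	1	none
M. sambiranensis	Sambirano	1	1	1.0	0.149	0	0	0	12:0.98,15:0.02	1	none
M. mittermeieri	Mittermeieri	1	1	1.0	0	0	0	0	14:0.97,15:0.03	1	none
M. lehilahytsara	Lehilahytsara	1	1	1.0	0	0	0	0	14:0.04,15:0.95,18:0.01	1	none
M. berthae	Berthae	1	1	1.0	0	0	0	0	16:0.91,17:0.04,18:0.02,19:0.03	1	geographic-override
M. rufus	Ranomafana	1	1	0.0	0	0	0	0	8:0.01,16:0.12,17:0.78,18:0.02,19:0.07	1	geographic-override
M. myoxinus	Myoxinus	1	1	0.77	0	0	0	0	8:0.01,17:0.01,18:0.36,19:0.62	1	geographic-override
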