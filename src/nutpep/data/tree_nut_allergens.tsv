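accession	allergen_name	species	protein_type	domain_ids	domain_set
Q8L5L5	Ana o 1.0101	Anacardium occidentale	7S vicilin	IPR006045;IPR014710;IPR011051	3a
Q8L5L6	Ana o 1.0102	Anacardium occidentale	7S vicilin	IPR006045;IPR014710;IPR011051	3a
Q8GZP6	Ana o 2.0101	Anacardium occidentale	11S legumin	IPR022379;IPR006044;IPR006045;IPR014710;IPR011051	3b
Q8H2B8	Ana o 3.0101	Anacardium occidentale	2S albumin	IPR036312;IPR016140;IPR000617	1
Q84XA9	Car i 1.0101	Carya illinoinensis	2S albumin	IPR036312;IPR016140;IPR000617	1
B3STU4	Car i 2.0101	Carya illinoinensis	7S vicilin	IPR006045;IPR014710;IPR011051;IPR006792	2
B5KVH4	Car i 4.0101	Carya illinoinensis	11S legumin	IPR022379;IPR006044;IPR006045;IPR014710;IPR011051	3b
P93198	Jug r 1.0101	Juglans regia	2S albumin	IPR036312;IPR016140;IPR000617	1
Q9SEW4	Jug r 2.0101	Juglans regia	7S vicilin	IPR006045;IPR014710;IPR011051;IPR006792	2
C5H617	Jug r 3	Juglans regia	non-specific lipid transfer protein type 1	IPR036312;IPR016140;IPR000528	none
Q2TPW5	Jug r 4.0101	Juglans regia	11S legumin	IPR022379;IPR006044;IPR006045;IPR014710;IPR011051	3b
B7P072	Pis v 1.0101	Pistacia vera	2S albumin	IPR036312;IPR016140;IPR000617	1
B7P073	Pis v 2.0101	Pistacia vera	11S legumin	IPR022379;IPR006044;IPR006045;IPR014710;IPR011051	3b
B7P074	Pis v 2.0201	Pistacia vera	11S legumin	IPR022379;IPR006044;IPR006045;IPR014710;IPR011051	3b
B4X640	Pis v 3.0101	Pistacia vera	7S vicilin	IPR006045;IPR014710;IPR011051	3a
B2BDZ8	Pis v 4.0101	Pistacia vera	manganese superoxide dismutase	IPR001189;IPR019833;IPR019832;IPR019831;IPR036324;IPR036314	none
B7SLJ1	Pis v 5.0101	Pistacia vera	11S legumin	IPR006044;IPR006045;IPR014710;IPR011051	3b
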