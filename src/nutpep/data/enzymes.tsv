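name	ec_number	biopep_id	p1_residues	p1prime_exclusions
pepsin_ph_gt2	3.4.23.1	39	FL
trypsin	3.4.21.4	12	KR
chymotrypsin_a	3.4.21.1	11	FYW
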