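# ArsC-domain (PF03960) residue signatures, E. coli ArsC (P08692) numbering.
# columns: signature_name	ref_position	allowed_residues	kind
conserved	94	R	required
conserved	95	P	required
conserved	106	CG	required
set1	60	R	required
set1	107	R	required
set1	108	P	required
set2	8	H	required
set2	9	N	required
set2	15	S	required
set3	12	C	required
set3	22	LI	required
set4	93	K	required
set4	60	N	required
spx_like	106	G	required
spx_like	60	R	forbidden
spx_like	107	R	forbidden
spx_like	108	P	forbidden
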