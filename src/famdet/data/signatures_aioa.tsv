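# Molybdopterin oxidoreductase domain (PF00384) highly conserved residues,
# A0A0U0D0V4 numbering (13 positions; AioA identification additionally needs
# similarity comparison — conserved positions alone are shared across the family).
# columns: signature_name	ref_position	allowed_residues	kind
conserved	112	R	required
conserved	116	P	required
conserved	167	W	required
conserved	170	A	required
conserved	258	G	required
conserved	287	P	required
conserved	307	D	required
conserved	518	A	required
conserved	557	G	required
conserved	563	G	required
conserved	778	L	required
conserved	779	P	required
conserved	785	E	required
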