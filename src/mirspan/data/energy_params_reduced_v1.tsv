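# Reduced nearest-neighbor RNA parameter set, 37 C, kcal/mol.
# Watson-Crick stacking terms follow published Turner-style values; stacks
# involving G:U pairs use pooled values (gu_stack: one G:U in the quartet,
# gugu_stack: two) rather than motif-specific tables.  Loop costs are
# affine.  Stack keys are 'XY/ZW': strand1 5'->3' XY, strand2 3'->5' ZW,
# i.e. outer pair X:Z, inner pair Y:W; symmetry partners are implied.
kind	key	value
meta	version	reduced-v1
scalar	duplex_init	4.09
scalar	hairpin_init	5.4
scalar	hairpin_per_nt	0.3
scalar	bulge_init	3.8
scalar	bulge_per_nt	0.4
scalar	internal_init	4.0
scalar	internal_per_nt	0.35
scalar	multi_init	3.4
scalar	multi_branch	0.4
scalar	multi_unpaired	0.0
scalar	min_hairpin	3
scalar	max_loop	15
scalar	gu_stack	-1.2
scalar	gugu_stack	-0.4
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
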