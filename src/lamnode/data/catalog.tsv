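# Pathogenic LN-domain missense mutation catalog (23 entries).
# Columns: subunit, author-numbered position, wild-type and mutant residue
# (1-letter), trimeric node construct, associated disorder, and the
# literature class label.  The last column is consumed only by the
# evaluation harness, never by the classifier.
subunit	position	wt	mut	node	disease	class_label_from_paper
alpha1	94	Q	R	a1(Q94R)b1g1	Poretti-Boltshauser syndrome	1
alpha2	138	Y	H	a2(Y138H)b1g1	LAMA2-CMD	1
alpha2	204	S	F	a2(S204F)b1g1	LAMA2-CMD	1
alpha2	277	S	L	a2(S277L)b1g1	LAMA2-CMD	1
alpha2	284	G	R	a2(G284R)b1g1	LAMA2-CMD	1
beta1	269	G	R	a2b1(G269R)g1	developmental heart disorder	1
beta2	48	Y	S	a5b2(Y48S)g1	Pierson syndrome	1
beta2	80	S	R	a5b2(S80R)g1	Pierson syndrome	1
beta2	147	H	R	a5b2(H147R)g1	Pierson syndrome	1
beta2	179	S	F	a5b2(S179F)g1	Pierson syndrome	1
alpha5	286	R	L	a5(R286L)b2g1	developmental disorders of kidney, face and limbs	1
alpha2	157	S	F	a2(S157F)b1g1	LAMA2-CMD	2
beta2	167	D	Y	a5b2(D167Y)g1	Pierson syndrome	2
beta2	246	R	Q	a5b2(R246Q)g1	Pierson syndrome	2
beta2	246	R	W	a5b2(R246W)g1	Pierson syndrome	2
alpha2	83	C	R	a2(C83R)b1g1	LAMA2-CMD	3
alpha2	86	C	Y	a2(C86Y)b1g1	LAMA2-CMD	3
beta2	321	C	R	a5b2(C321R)g1	Pierson syndrome	3
alpha2	393	C	G	a2(C393G)b1g1	LGMD	3
alpha2	152	W	G	a2(W152G)b1g1	LGMD	4
alpha2	167	Q	P	a2(Q167P)b1g1	LGMD	4
alpha2	243	L	P	a2(L243P)b1g1	LGMD	4
beta2	139	L	P	a5b2(L139P)g1	Pierson syndrome	4
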