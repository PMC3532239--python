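type	distance	allele	gene	change
critical_splice_donor	1	aoba	Col4a4	G>A
critical_splice_donor	1	bat	Frem1	T>C
critical_splice_donor	1	bullet_gray	Ap3b1	G>T
critical_splice_donor	1	mister_clean	Hr	G>A
critical_splice_donor	1	tortellini	Tgm3	G>A
critical_splice_donor	1	warmflash	Flt3	G>A
critical_splice_donor	1	zuckerkuss	Slc45a2	G>T
critical_splice_donor	2	drunk	Agtpbp1	T>A
critical_splice_donor	2	feeble	Slc15a4	T>A
critical_splice_donor	2	frazz	Dock2	T>A
critical_splice_donor	2	frog	Epha4	T>C
critical_splice_donor	2	iron-man	Trfr2	T>C
critical_splice_donor	2	seal	Col1a1	T>A
critical_splice_donor	2	souris	Lyst	T>A
critical_splice_donor	2	styx	Inpp5d	T>A
critical_splice_donor	2	toffee	Hps5	T>C
critical_splice_donor	2	wobbley	Atcay	T>A
noncritical_splice_donor	3	salt_and_pepper	Dtnbp1	A>T
noncritical_splice_donor	5	nut	Myo5a	G>A
noncritical_splice_donor	5	odd	Lepr	G>T
noncritical_splice_donor	6	atchoum	Eif2ak4	T>C
critical_splice_acceptor	2	Joker	Itgb2	A>T
critical_splice_acceptor	2	mask	Tmprss6	A>G
critical_splice_acceptor	2	rio	Agtpbp1	A>G
critical_splice_acceptor	2	torpid	Tirap	A>T
noncritical_splice_acceptor	5	Sluggish	Map3k8	T>A
noncritical_splice_acceptor	7	Minnie	Muted	T>A
noncritical_splice_acceptor	8	splotch2	Adamts20	T>A
noncritical_splice_acceptor	11	frizz	Dock2	T>A
noncritical_splice_acceptor	13	poison	Stat1	T>A
noncritical_splice_acceptor	17	koala	Mlph	A>G
splice_donor_created	57	jinx	Unc13d	C>A
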