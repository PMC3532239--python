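category	phenotypic_total	phenotypic_pct	incidental_total	incidental_pct
missense	111	62.1	330	82.0
noncritical_splice_donor	5	2.8	22	5.5
noncritical_splice_acceptor	6	3.4	22	5.5
nonsense	35	19.8	19	4.7
critical_splice_donor	17	26.6	8	2.0
critical_splice_acceptor	4	2.2	1	0.3
total	178	NA	402	NA
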