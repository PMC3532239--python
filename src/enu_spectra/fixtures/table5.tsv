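substitution	p	phenotypic_k	phenotypic_P	incidental_k	incidental_P	combined_k	combined_P
A>T	0.5470	23	0.00397	39	0.000435	62	0.00000725
T>A	0.4530	39	NA	64	NA	103	NA
A>G	0.5780	20	0.00071	70	0.9425	90	0.00322
T>C	0.4220	36	NA	66	NA	102	NA
A>C	0.5308	2	0.06310	8	0.3982	10	0.09730
T>G	0.4692	7	NA	9	NA	16	NA
G>T	0.5341	10	0.6600	14	0.3876	24	0.4289
C>A	0.4659	8	NA	15	NA	23	NA
G>A	0.5563	9	0.1202	35	0.1401	44	0.0533
C>T	0.4437	13	NA	37	NA	50	NA
G>C	0.5187	0	NA	1	1.0	1	1.0
C>G	0.4813	0	NA	0	NA	0	NA
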