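substitution	coding	splice	total
A>C	7557737	147033	7704770
A>G	6938327	147033	7085360
A>T	7856324	147033	8003357
C>A	6939729	93629	7033358
C>G	7387012	93629	7480641
C>T	5071174	93629	5164803
G>A	6231339	243302	6474641
G>C	7818308	243302	8061610
G>T	7818308	243302	8061610
T>A	6415261	212884	6628145
T>C	4959605	212884	5172489
T>G	6597408	212884	6810292
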