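chromosome	length	p_end
chr1	30000000	15000000
chr2	20000000	10000000
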