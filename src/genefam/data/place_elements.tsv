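element_id	pattern	category
S000415	ACGTG	drought
S000453	GAAAAA	salinity
S000030	CCAAT	heat
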