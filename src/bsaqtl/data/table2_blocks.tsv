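block	strain	chrom	start	end
1	442 ChrXVI.b1	ChrXVI	79486	85523
2	442 ChrXVI.b2	ChrXVI	85504	91015
5	442 ChrXVI.b5	ChrXVI	101093	104721
6	442 ChrXVI.b6	ChrXVI	104702	108350
7	442 ChrXVI.b7	ChrXVI	108331	114729
8	442 ChrXVI.b8	ChrXVI	114710	119641
9	442 ChrXVI.b9	ChrXVI	119622	125450
10	442 ChrXVI.b10	ChrXVI	125432	129615
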