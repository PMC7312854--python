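gene	hgvs_c	hgvs_p	rsid	note
BRCA1	c.4957G>T	p.V1653L	rs80357261	
BRCA1	c.4957G>A	p.V1653M	rs80357261	
BRCA1	c.3283A>G	p.K1095E		
BRCA1	c.3707A>G	p.N1236S	rs863224760	
BRCA1	c.4093C>G	p.L1365V	rs1567788936	
BRCA2	c.520C>T	p.R174C	rs41293469	
BRCA2	c.1744A>C	p.T582P	rs80358457	
BRCA2	c.2350A>G	p.M784V	rs11571653	
BRCA2	c.3067_3072del	p.N1023_I1024del	rs730881605	
BRCA2	c.5158A>G	p.I1720V		synthetic
BRCA2	c.6131G>T	p.G2044V	rs56191579	
BRCA2	c.6322C>T	p.R2108C	rs55794205	
BRCA2	c.8023A>G	p.I2675V	rs397507954	
BRCA2	c.9155G>A	p.R3052Q	rs80359171	
BRCA2	c.10219del	p.N3407fs		
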