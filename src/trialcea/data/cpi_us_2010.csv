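year,cpi_u,factor_to_2010
1995,152.4,1.430814
1996,156.9,1.389777
1997,160.5,1.358604
1998,163.0,1.337767
1999,166.6,1.30886
2000,172.2,1.266295
2001,177.1,1.231259
2002,179.9,1.212096
2003,184.0,1.185087
2004,188.9,1.154346
2005,195.3,1.116518
2006,201.6,1.081627
2007,207.342,1.051673
2008,215.303,1.012787
2009,214.537,1.016403
2010,218.056,1.0
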