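# Reduced amino-acid alphabet registry: name <TAB> size <TAB> grouping string.
# A grouping string is a whitespace-separated list of groups; a group is a
# single residue letter or a bracketed run of residues sharing one symbol.
all.20	20	P G E K R Q D S N T H C I V W Y F A L M
dssp.5	5	[AEHKQR] [FILMVWY] [CST] [DN] [GP]
dssp.10	10	[EKQR] [IV] [LY] F [AM] W [HT] C [DNS] [GP]
gbmr.4	4	G [ADEKNQRST] [CFHILMVWY] P
gbmr.10	10	G D N [AEFIKLMQRVW] Y H C T S P
hsdm.5	5	[LIVFMY] W C [DNTSKEQRAGP] H
sdm.6	6	[YFLIVM] C W [DNTSQKERAG] H P
murphy.5	5	[LVIMC] [ASGTP] [FYW] [EDNQ] [KRH]
murphy.10	10	A [KR] [EDNQ] C G H [ILVM] [FYW] P [ST]
td.5	5	[PG] [EKRQ] [DSNTHC] [IVWYF] [ALM]
td.10	10	P G [EKRQ] [DSN] T [HC] [IV] [WYF] A [LM]
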