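# Curated breast-cancer actionability knowledge base (synthetic, seeded from
# well-known drug-gene pairs; replaceable with a site-specific table).
# drugs and oncogenic_classes are '|'-separated.
gene	matcher	protein_change	tumor_context	level	drugs	oncogenic_classes
PIK3CA	exact_protein_change	p.H1047R	breast	L1	alpelisib|fulvestrant
PIK3CA	exact_protein_change	p.E545K	breast	L1	alpelisib|fulvestrant
PIK3CA	exact_protein_change	p.E542K	breast	L1	alpelisib|fulvestrant
BRCA1	truncating		breast	L1	olaparib|talazoparib
BRCA2	truncating		breast	L1	olaparib|talazoparib
ERBB2	amplification		breast	L1	trastuzumab|pertuzumab|ado-trastuzumab emtansine|lapatinib|neratinib
AKT1	exact_protein_change	p.E17K	breast	L3A	capivasertib|ipatasertib
ESR1	any_oncogenic		breast	L3A	fulvestrant	missense
PTEN	truncating		breast	L3A	capivasertib
ERBB2	any_oncogenic		breast	L3A	neratinib	missense|inframe_indel
CDKN2A	any_oncogenic		other	L3B	palbociclib|ribociclib|abemaciclib	nonsense|frameshift|splice_site|missense
FGFR1	amplification		other	L3B	erdafitinib
KRAS	any_oncogenic		other	L3B	sotorasib	missense
NF1	any_oncogenic		other	L4	selumetinib	nonsense|frameshift|splice_site|missense
NF2	any_oncogenic		other	L4	verteporfin	nonsense|frameshift|splice_site|missense
TSC2	truncating		other	L3B	everolimus
MTOR	any_oncogenic		other	L4	everolimus	missense
STK11	truncating		other	L4	everolimus
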