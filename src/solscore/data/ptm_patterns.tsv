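# Built-in PTM-site / sequence-motif catalogue.
# One pattern per line: name<TAB>PROSITE-syntax pattern<TAB>feature kind.
# kind "discrete" -> per-sequence site count; "binary" -> presence/absence.
# Classical PROSITE consensus patterns; accession noted above each entry.
# The catalogue is user-editable and user-extensible.
#
# PS00001 N-glycosylation site
n_glycosylation	N-{P}-[ST]-{P}	discrete
# PS00004 cAMP- and cGMP-dependent protein kinase phosphorylation site
pka_phosphosite	[RK](2)-x-[ST]	discrete
# PS00005 protein kinase C phosphorylation site
pkc_phosphosite	[ST]-x-[RK]	discrete
# PS00006 casein kinase II phosphorylation site
ck2_phosphosite	[ST]-x(2)-[DE]	discrete
# PS00008 N-myristoylation site
myristoylation	G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}	discrete
# PS00009 amidation site
amidation	x-G-[RK]-[RK]	discrete
# PS00010 aspartic acid / asparagine hydroxylation site (EGF-domain context)
asx_hydroxylation	C-x-[DN]-x(4)-[FY]-x-C-x-C	binary
# Simplified acidic-context rule for tyrosine sulfation (editable)
sulfation_context	[DE]-x(2)-Y-x(2)-[DE]	discrete
# PS00294 prenylation: C-terminal CaaX box
prenylation_caax	C-{DENQ}-[LIVM]-x>	binary
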