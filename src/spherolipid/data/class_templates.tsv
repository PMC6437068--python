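# Lipid class templates: residue-level backbone formula plus chain-position bookkeeping.
# core_formula is the neutral molecule with every chain position hydrolyzed off
# (for sphingolipid classes it is the residual after subtracting the C_nH_(2n-2d)
# hydrocarbon contribution of base + N-acyl).  n_positions counts chain positions,
# n_ether of which are ether-linked alkyls; sphingoid=1 marks sphingoid-base classes
# whose shorthand carries the d-prefix (di-hydroxy base).  adducts lists default
# ionization, first entry = quantified/identified adduct.
lipid_class	backbone	core_formula	n_positions	n_ether	sphingoid	adducts
LPC	glycerophospholipid	C8H20NO6P	1	0	0	[M+HCOO]-;[M+H]+
PC	glycerophospholipid	C8H20NO6P	2	0	0	[M+HCOO]-;[M+H]+
PC O-	glycerophospholipid	C8H20NO6P	2	1	0	[M+HCOO]-;[M+H]+
PE	glycerophospholipid	C5H14NO6P	2	0	0	[M-H]-;[M+H]+
PE O-	glycerophospholipid	C5H14NO6P	2	1	0	[M-H]-;[M+H]+
TG	glycerolipid	C3H8O3	3	0	0	[M+NH4]+;[M+Na]+
SM	sphingolipid	C5H13N2O6P	2	0	1	[M+HCOO]-;[M+H]+
Cer	sphingolipid	HNO3	2	0	1	[M-H]-;[M+H]+
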