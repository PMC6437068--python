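# Default class-diagnostic MS/MS evidence, one row per (lipid class, polarity).
# Tokens: ion:<formula><+|->  fixed-m/z diagnostic ion
#         loss:<formula>      neutral loss from the precursor
#         mz:<number>         literal m/z
# Phosphocholine-headgroup classes are read out as formate adducts via the
# demethylated headgroup anion (C4H11NO4P-, m/z 168.043) and the methyl-formate
# neutral loss; PE classes via the ethanolamine-phosphate anions; ceramide via
# water/formaldehyde losses; TG as ammonium adducts losing NH3.  The table is
# ordinary data and can be replaced wholesale by the user.
lipid_class	polarity	required	min_required	forbidden
LPC	-	ion:C4H11NO4P-;loss:C2H4O2	1	ion:C2H7NO4P-;ion:C5H11NO5P-
PC	-	ion:C4H11NO4P-;loss:C2H4O2	1	ion:C2H7NO4P-;ion:C5H11NO5P-
PC O-	-	ion:C4H11NO4P-;loss:C2H4O2	1	ion:C2H7NO4P-;ion:C5H11NO5P-
SM	-	ion:C4H11NO4P-;loss:C2H4O2	1	ion:C2H7NO4P-;ion:C5H11NO5P-
PE	-	ion:C2H7NO4P-;ion:C5H11NO5P-	1	ion:C4H11NO4P-
PE O-	-	ion:C2H7NO4P-;ion:C5H11NO5P-	1	ion:C4H11NO4P-
Cer	-	loss:H2O;loss:CH2O	1	ion:C4H11NO4P-;ion:C2H7NO4P-
TG	+	loss:NH3	1	ion:C5H15NO4P+
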