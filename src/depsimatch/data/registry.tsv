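composition_key	names	isomer_group	confidence	note
Hiv,Hiv,Hiv|161,161,161	BEA	BEA	text_defined	beauvericin
Hiv,Hiv,Hmp|161,161,161	BEA A;BEA F;ALLOBEA A	BEA A/F/ALLOBEA A	text_defined	positional isomers; not distinguishable by MS
Hiv,Hmp,Hmp|161,161,161	BEA B;ALLOBEA B	BEA B/ALLOBEA B	text_defined	positional isomers; not distinguishable by MS
Hmp,Hmp,Hmp|161,161,161	BEA C;ALLOBEA C	BEA C/ALLOBEA C	text_defined	positional isomers; not distinguishable by MS
Hiv,Hiv,Hiv|113,161,161	BEA E	BEA E	table_derived	reported -127 Da loss suggests an N-Me-Leu/Ile residue, but composition C41H57N3O9 requires the 113 class
Hbu,Hiv,Hiv|161,161,161	BEA G1	BEA G1	text_defined	one D-Hbu unit
Hbu,Hbu,Hiv|161,161,161	BEA G2	BEA G2	text_defined	two D-Hbu units
Hiv,Hiv,Hiv|113,113,161	BEAE B	BEAE B	table_derived	textual description (one N-Me-Val, two N-Me-Phe) conflicts with C37H57N3O9, which needs 113,113,161
Hiv,Hiv,Hmp|113,127,161	BEAE G1;BEAE G2;BEAE G3	BEAE G1/G2/G3	table_derived	only C39H61N3O9 multiset containing a single D-Hmp in place of D-Hiv
Hiv,Hiv,Hiv|113,127,161	BEAE *	BEAE *	text_defined	previously unreported analogue
Hiv,Hiv,Hiv|127,127,127	ENN A	ENN A	text_defined	enniatin A
Hiv,Hiv,Hiv|113,127,127	ENN A1	ENN A1	text_defined	enniatin A1
Hiv,Hiv,Hiv|113,113,127	ENN B1	ENN B1	text_defined	enniatin B1
Hiv,Hiv,Hiv|113,113,113	ENN B	ENN B	text_defined	enniatin B
-	BEA D	BEA D	name_only	composition not stated in available sources
-	BEA J	BEA J	name_only	composition not stated in available sources
-	BEA K	BEA K	name_only	composition not stated in available sources
-	BEA L	BEA L	name_only	composition not stated in available sources
-	BEAE A	BEAE A	name_only	composition not stated in available sources
-	BEAE L	BEAE L	name_only	composition not stated in available sources
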