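# toy duplex model for tests: WC stack -2, GU stack -1,
# no loops, no initiation, temperature-independent (dH = dG)
pair	AU	-	-
pair	UA	-	-
pair	GC	-	-
pair	CG	-	-
pair	GU	-	-
pair	UG	-	-
stack	AA/UU	-2.0	-2.0
stack	AU/UA	-2.0	-2.0
stack	AG/UC	-2.0	-2.0
stack	AC/UG	-2.0	-2.0
stack	AG/UU	-1.0	-1.0
stack	AU/UG	-1.0	-1.0
stack	UA/AU	-2.0	-2.0
stack	UU/AA	-2.0	-2.0
stack	UG/AC	-2.0	-2.0
stack	UC/AG	-2.0	-2.0
stack	UG/AU	-1.0	-1.0
stack	UU/AG	-1.0	-1.0
stack	GA/CU	-2.0	-2.0
stack	GU/CA	-2.0	-2.0
stack	GG/CC	-2.0	-2.0
stack	GC/CG	-2.0	-2.0
stack	GG/CU	-1.0	-1.0
stack	GU/CG	-1.0	-1.0
stack	CA/GU	-2.0	-2.0
stack	CU/GA	-2.0	-2.0
stack	CG/GC	-2.0	-2.0
stack	CC/GG	-2.0	-2.0
stack	CG/GU	-1.0	-1.0
stack	CU/GG	-1.0	-1.0
stack	GA/UU	-1.0	-1.0
stack	GU/UA	-1.0	-1.0
stack	GG/UC	-1.0	-1.0
stack	GC/UG	-1.0	-1.0
stack	GG/UU	-1.0	-1.0
stack	GU/UG	-1.0	-1.0
stack	UA/GU	-1.0	-1.0
stack	UU/GA	-1.0	-1.0
stack	UG/GC	-1.0	-1.0
stack	UC/GG	-1.0	-1.0
stack	UG/GU	-1.0	-1.0
stack	UU/GG	-1.0	-1.0
init	-	0	0
loop_open	-	inf	0
loop_ext	-	0	0
max_loop_span	-	15	-
temperature_c	-	37	-
temperature_ref_c	-	37	-
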