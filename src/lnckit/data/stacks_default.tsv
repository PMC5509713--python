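# nearest-neighbor RNA-RNA duplex parameters (kcal/mol)
# Turner-style WC stack dG(37C)/dH values; GU-containing stacks
# fall back to default_stack. Mirrored contexts are filled by symmetry.
pair	AU	-	-
pair	UA	-	-
pair	GC	-	-
pair	CG	-	-
pair	GU	-	-
pair	UG	-	-
stack	AA/UU	-0.93	-6.82
stack	AU/UA	-1.1	-9.38
stack	UA/AU	-1.33	-7.69
stack	CU/GA	-2.08	-10.48
stack	CA/GU	-2.11	-10.44
stack	GU/CA	-2.24	-11.4
stack	GA/CU	-2.35	-12.44
stack	CG/GC	-2.36	-10.64
stack	GG/CC	-3.26	-13.39
stack	GC/CG	-3.42	-14.88
default_stack	-	-0.5	-3.0
init	-	4.09	3.61
loop_open	-	8.0	0
loop_ext	-	0.8	0
max_loop_span	-	15	-
temperature_c	-	25	-
temperature_ref_c	-	37	-
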