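pair5p	pair3p	dG
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-0.55
AU	UG	-1.36
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-1.27
UA	UG	-1.00
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-1.41
CG	UG	-2.11
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-2.51
GC	UG	-1.53
GU	AU	-1.00
GU	UA	-1.36
GU	CG	-1.53
GU	GC	-2.11
GU	GU	-0.50
GU	UG	0.47
UG	AU	-1.27
UG	UA	-0.55
UG	CG	-2.51
UG	GC	-1.41
UG	GU	0.30
UG	UG	-0.50
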