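# RNA nearest-neighbor helix stacking free energies, delta-G at 37 C (kcal/mol).
# top: 5'->3' dinucleotide; bottom: the paired bases written 3'->5' under the
# top (bottom[i] pairs top[i]).  Watson-Crick/Watson-Crick stacks carry the
# standard Turner values; stacks involving a G:U wobble pair are approximated
# by a single weak constant (and 0.0 for the destabilizing 5'GU/3'UG motif),
# clamped at <= 0 so duplex energy is monotone under extension.
top	bottom	dg
AA	UU	-0.93
UU	AA	-0.93
AU	UA	-1.10
UA	AU	-1.33
CU	GA	-2.08
AG	UC	-2.08
CA	GU	-2.11
UG	AC	-2.11
GU	CA	-2.24
AC	UG	-2.24
GA	CU	-2.35
UC	AG	-2.35
CG	GC	-2.36
GG	CC	-3.26
CC	GG	-3.26
GC	CG	-3.42
AG	UU	-0.50
AU	UG	-0.50
UG	AU	-0.50
UU	AG	-0.50
CG	GU	-0.50
CU	GG	-0.50
GG	CU	-0.50
GU	CG	-0.50
GA	UU	-0.50
GU	UA	-0.50
GC	UG	-0.50
GG	UC	-0.50
GG	UU	-0.50
GU	UG	0.00
UA	GU	-0.50
UU	GA	-0.50
UC	GG	-0.50
UG	GC	-0.50
UG	GU	-0.50
UU	GG	-0.50
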