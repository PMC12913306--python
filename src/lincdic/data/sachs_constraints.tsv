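cause	target	kind	delta
PKC	Jnk	+
PKC	P38	+
PIP3	Akt	+
PKA	P38	-
PKA	Raf	-
Raf	Erk	+
Raf	Mek	+
Mek	Erk	+
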