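organism	group	gac	gat
Lumbricus terrestris	Oligochaeta	34	40
Perionyx excavatus	Oligochaeta	42	32
Tonoscolex birmanicus	Oligochaeta	41	28
Amynthas aspergillus	Oligochaeta	43	28
Metaphire vulgaris	Oligochaeta	32	40
Whitmania pigra	Hirudinea	12	78
Haementeria officinalis	Hirudinea	8	58
Placobdella parasitica	Hirudinea	14	56
Placobdella lamothei	Hirudinea	27	45
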