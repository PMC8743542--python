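# Nearest-neighbor stacking free energies for DNA/DNA helices, kJ/mol.
# Keyed by the 5'->3' top-strand dinucleotide of a Watson-Crick stack
# (bottom strand is the complement). Values are the SantaLucia unified
# NN dG(37C) set converted from kcal/mol; the WOBBLE entry is a single
# flat stack value applied whenever either pair of the stack is a G.T
# wobble (a coarse stand-in: per-context wobble stacks are not modelled).
# Editable: the folding engine reads this file at import time.
NN	AA	-4.18
NN	TT	-4.18
NN	AT	-3.68
NN	TA	-2.43
NN	CA	-6.07
NN	TG	-6.07
NN	GT	-6.02
NN	AC	-6.02
NN	CT	-5.36
NN	AG	-5.36
NN	GA	-5.44
NN	TC	-5.44
NN	CG	-9.08
NN	GC	-9.37
NN	GG	-7.70
NN	CC	-7.70
WOBBLE	-	-1.50
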