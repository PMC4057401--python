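# DNA nearest-neighbor free-energy parameter table, version 1 (37 C, kcal/mol).
# kind	key	value
# stack keys are "XY/WZ": top strand 5'-XY-3' over bottom strand 3'-WZ-5',
#   i.e. the outer pair is X:W and the inner (stacked) pair is Y:Z.
#   Only the 10 unique Watson-Crick contexts are listed; the symmetric
#   context "ZW/YX" is derived at load time.
# hairpin/bulge/internal keys are loop sizes (unpaired nucleotides); sizes
#   beyond the table are extrapolated with a Jacobson-Stockmayer log term.
# multibranch: a = closure, b = per branch, c = per unpaired nucleotide.
# wobble_stack: flat term for any stack step involving a G:T pair.
stack	AA/TT	-1.00
stack	AT/TA	-0.88
stack	TA/AT	-0.58
stack	CA/GT	-1.45
stack	GT/CA	-1.44
stack	CT/GA	-1.28
stack	GA/CT	-1.30
stack	CG/GC	-2.17
stack	GC/CG	-2.24
stack	GG/CC	-1.84
wobble_stack	any	-0.30
hairpin	3	3.50
hairpin	4	3.50
hairpin	5	3.30
hairpin	6	4.00
hairpin	7	4.20
hairpin	8	4.30
hairpin	9	4.50
hairpin	10	4.60
bulge	1	4.00
bulge	2	2.90
bulge	3	3.10
bulge	4	3.20
bulge	5	3.30
bulge	6	3.50
bulge	7	3.70
bulge	8	3.80
bulge	9	3.90
bulge	10	4.00
internal	2	3.20
internal	3	3.60
internal	4	4.00
internal	5	4.40
internal	6	4.40
internal	7	4.60
internal	8	4.80
internal	9	4.90
internal	10	5.00
multibranch	a	3.40
multibranch	b	0.40
multibranch	c	0.10
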