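YN00 synthetic_example.nuc

Synthetic stand-in for a PAML 4.x yn00 main result file (hand-written to
mirror the layout; the numbers are not from a real PAML run).

ns =   3	ls = 100

(A) Nei-Gojobori (1986) method

Nei M, Gojobori T (1986) Simple methods for estimating the numbers of
synonymous and nonsynonymous nucleotide substitutions. Mol Biol Evol 3:418-426.

Nei & Gojobori 1986. dN/dS (dN, dS)

geneA
geneB               0.2210 (0.0321, 0.1452)
geneC               0.3105 (0.0512, 0.1649)   0.2871 (0.0450, 0.1567)


(B) Yang & Nielsen (2000) method

Yang Z, Nielsen R (2000) Estimating synonymous and nonsynonymous substitution
rates under realistic evolutionary models. Mol. Biol. Evol. 17:32-43

Data used as pairwise comparison:
2 (geneB) vs. 1 (geneA)
3 (geneC) vs. 1 (geneA)
3 (geneC) vs. 2 (geneB)

seq. seq.     S       N        t   kappa   omega     dN +- SE    dS +- SE

   2    1    67.4   232.6   0.1087  3.2002  0.2310  0.0315 +- 0.0075  0.1364 +- 0.0265
   3    1    66.9   233.1   0.1402  3.1257  0.3120  0.0498 +- 0.0094  0.1596 +- 0.0291
   3    2    67.1   232.9   0.1315  3.0881  0.2904  0.0441 +- 0.0089  0.1519 +- 0.0283
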