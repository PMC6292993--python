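# gcaa — GC content and amino-acid usage in microbial protein evolution

`gcaa` is a desk-scale pipeline for studying how genomic GC content shapes
amino-acid usage as bacterial and archaeal proteins diverge from a low-GC
reference organism. Homologous protein-coding genes drift toward the GC
content their host genome prefers; because the genetic code maps GC-rich
codons to one set of amino acids (Ala, Gly, Pro, Arg) and AT-rich codons to
another (Phe, Ile, Lys, Met, Asn, Tyr), that nucleotide-level drift leaves a
measurable imprint on protein composition and on the nonsynonymous
substitution rate. The package is aimed at molecular-evolution researchers
who want every stage of that analysis — orthology, rate estimation,
composition statistics, regression — in one tested, reproducible toolkit,
with a codon-level simulator supplying ground-truth data so each stage can
be validated without downloading hundreds of genomes.

## What it computes

**Ortholog pairing.** Reciprocal best hits between a reference proteome and
each target proteome, scored by affine-gap pairwise alignment (BLOSUM62,
gap open 11 / extend 1), with identity ≥ 30% and ≥ 80% of the reference
residues aligned. Pre-computed BLAST tabular (outfmt 6) input is supported,
where the E < 10⁻⁵ criterion also applies.

**Evolutionary rate (Ka/Ks), Nei–Gojobori 1986.** Each sense codon
contributes synonymous site counts s = Σᵢ (synonymous one-step changes at
position i)/3 and nonsynonymous counts n = 3 − s; changes to stop codons
are nonsynonymous. For a codon pair, observed differences are averaged over
all mutational orderings that avoid stop codons. With pN = Nd/N and
pS = Sd/S, rates are Jukes–Cantor corrected:

    Ka = -(3/4) · ln(1 - 4·pN/3),   Ks = -(3/4) · ln(1 - 4·pS/3)

undefined (flagged, never numeric) when p ≥ 3/4. Protein alignments are
back-translated onto the original codons, so rates are computed in frame.
A PAML `yn00` output reader is included for parity checks.

**Deviation statistics.** For each homolog, ΔAA is its 20-vector of
amino-acid frequencies minus the reference homolog's (positive = gained),
and ΔGC is the GC-percent difference in percentage points. Group sums over
the GC-rich {A,G,P,R}, AT-rich {F,I,K,M,N,Y}, ancient {D,V,S,E,L,T} and
late-recruited {Q,H,C,W} sets, ΔGC binning (edges 0/5/10), Welch-test group
contrasts, and per-record correlations of ΔAA against amino-acid features.

**Association models.** Per-family Pearson correlation of gene GC percent
with Ka (families need ≥ 8 usable homologs; Benjamini–Hochberg q-values
reported alongside raw p); principal-component regression of Ka on the 20
composition fractions (centered, 6 components by default) with the first
component correlated against GC; ridge regression with a cross-validated
penalty and permutation-calibrated selection of contributing amino acids;
and the pairwise correlations within the amino-acid feature table
(codon GC class, recruitment order, synthesis cost, molecular weight).

**Simulator.** `simulate_study` evolves gene families from a common
ancestor across genomes whose mutational GC targets span 0.30–0.70, with
purifying selection (nonsynonymous acceptance probability ω) and an exact
per-event substitution ledger, so estimator accuracy is measured against
known truth.

## Worked example

Two homologous 9-codon genes that differ by two third-position changes:

```python
from gcaa import kaks_from_genes, gc_content

a = "ATGGCTAAACGTGAAATTCTGTGGGGA"
b = "ATGGCGAAACGTGAGATTCTGTGGGGA"
res = kaks_from_genes(cds_a=a, cds_b=b, aligned_a="MAKREILWG", aligned_b="MAKREILWG")
print(f"N={res.n_sites:.4f} S={res.s_sites:.4f} Nd={res.nd:.1f} Sd={res.sd:.1f}")
print(f"pS={res.ps:.6f} Ka={res.ka:.6f} Ks={res.ks:.6f}")
print(f"GC(a)={gc_content(a).gc_percent:.2f}%  GC(b)={gc_content(b).gc_percent:.2f}%")
```

prints

```
N=21.3333 S=5.6667 Nd=0.0 Sd=2.0
pS=0.352941 Ka=0.000000 Ks=0.476992
GC(a)=44.44%  GC(b)=51.85%
```

Both substitutions are synonymous (Nd = 0, so Ka = 0); the two observed
synonymous differences on 5.67 synonymous sites give pS = 0.353, which the
Jukes–Cantor correction inflates to Ks = 0.477 — and the target gene's GC
has risen 7.4 points, GC change with no protein change.

The same analysis at study scale, from the shell:

```
gcaa simulate --out study --seed 4 --families 10 --genomes 12 --codons 60
gcaa run --study-dir study --out run --seed 4
# -> run complete: 112 ortholog pairs, 10 families tested
gcaa associate --run-dir run | head -3
# gene_name  n   r             p              q
# fam000     12  0.5866149068  0.04497153533  0.07495255889
# fam001     11  0.8221636034  0.001897130909 0.006323769697
```

Each row is one gene family: the Pearson correlation between homolog GC
percent and Ka across genomes, its p-value, and the Benjamini–Hochberg
q-value. The run directory also contains `orthologs.tsv`, `kaks.tsv`,
`deviations.tsv`, `deviation_bins.tsv`, `models.tsv` (PCR and ridge
summaries), `feature_correlations.tsv`, and `summary.json` with the config
hash and seed for exact re-runs.

## Layout

```
src/gcaa/
  records.py           gene records, FASTA I/O, gene-name lists
  features.py          GC content, composition, CV, amino-acid feature table
  orthology.py         pairwise alignment, RBH, BLAST-tabular reader
  codon_evolution.py   back-translation, NG86 Ka/Ks, yn00 reader
  deviation_stats.py   ΔAA/ΔGC records, binning, contrasts
  association_models.py  correlations, GC–Ka tables, PCR, ridge
  synthetic_data.py    GC-biased codon-evolution simulator
  pipeline.py, cli.py  orchestration and the `gcaa` command
docs/methods.md        model assumptions, parameter choices, limitations
```
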