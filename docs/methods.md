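# Methods

## The question and the measurement chain

Homologous protein-coding genes in bacteria and archaea drift toward the GC
content preferred by their host genome. Because codon GC is unevenly
distributed across the genetic code — Ala, Gly, Pro and Arg are encoded by
GC-rich codons, Phe, Ile, Lys, Met, Asn and Tyr by AT-rich ones — GC drift
is expected to (i) shift amino-acid composition along a GC axis and (ii)
show up as nonsynonymous divergence, i.e. a positive association between a
homolog's GC content and its Ka relative to a low-GC reference. The package
measures this chain end to end: ortholog calling, codon-aware rate
estimation, composition-deviation statistics, and regression models, with a
simulator that generates data under a known mechanism so every estimator
can be checked against ground truth.

## Ka/Ks estimation (Nei–Gojobori 1986)

Site counts: for a sense codon, each position contributes the fraction of
its three single-nucleotide changes that are synonymous; changes producing
a stop codon count as nonsynonymous. S + N = 3 per codon; pairwise counts
are the average of the two sequences' totals. Difference counts for codons
differing at 2–3 positions are averaged with equal weight over all
mutational orderings that avoid stop codons; if every ordering is blocked,
all are used. Proportions pN = Nd/N, pS = Sd/S are corrected for multiple
hits with the one-parameter Jukes–Cantor distance. When p ≥ 3/4 the
correction is undefined and the result carries a flag instead of a number;
flagged rows are excluded from downstream fits.

Two properties of this estimator matter for interpreting results:

* **Equal-path averaging creates a nonsynonymous floor.** Two synonymous
  events in one codon (Leu TTA → CTA → CTC) leave a codon pair whose two
  orderings are one all-synonymous and one all-nonsynonymous path, so NG86
  assigns Nd = 1.0 to a history with no amino-acid change. Consequently Ka
  is not exactly zero under fully purifying selection at finite synonymous
  divergence — with ω = 0 at this package's study conditions the observed
  Ka floor is ~0.004–0.02. The test suite asserts the exact content
  (identical proteins; Nd = 0 at every single-difference codon) separately
  from the idealized zero.
* **The JC correction assumes unbiased substitution**, which the GC-biased
  generator deliberately violates; this contributes spread but no material
  bias to the recovery analysis (ledger-rate correlation ≥ 0.97 at the
  default study scale).

Alignment for rate estimation is global (Needleman–Wunsch, BLOSUM62,
11/1 gaps) on proteins, back-translated onto the source codons with frame
and translation validation; gap or stop-containing columns are dropped
(pairwise deletion). Orthology search uses the local (Smith–Waterman)
variant of the same scoring, mimicking BLAST; coverage is measured against
the reference-role sequence.

## Amino-acid feature table

Shipped as `src/gcaa/data/aa_features.tsv`: codon GC class (0 = AT-rich,
1 = intermediate, 2 = GC-rich), recruitment order into the genetic code
(Trifonov's consensus chronology, rank 1 = oldest), biosynthetic cost in
ATP equivalents on the aerobic *E. coli* scale (Akashi & Gojobori), and
average residue molecular weight (Da). Derived groups: GC-rich {A,G,P,R},
AT-rich {F,I,K,M,N,Y}, and among intermediate-GC amino acids the ancient
{D,V,S,E,L,T} (rank ≤ 10) versus late-recruited {Q,H,C,W} (rank ≥ 11).
On this table the GC-rich group is significantly cheaper to synthesize
than the AT-rich group (Welch t, p = 0.0306), GC class anti-correlates
with recruitment order (R ≈ −0.67), and cost correlates with both order
(R ≈ 0.77) and weight (R ≈ 0.80).

## Deviation statistics

ΔAA = target composition − reference composition (sums to zero by
construction); ΔGC in percentage points. ΔGC bins use edges {0, 5, 10},
giving (−∞,0), [0,5), [5,10), [10,∞). Group contrasts use the Welch
(unequal-variance) t-test on values pooled one-per-record-per-amino-acid;
when both groups are exactly constant with equal means the contrast is
reported as t = 0, p = 1 rather than NaN. Per-record feature correlations
(ΔAA vs GC class, ΔAA vs recruitment order) skip constant records with a
warning and summarize the fraction of records significant at p < 0.05.

## Association models

* **Pearson everywhere**, two-sided p from the t distribution with n−2 df;
  p-values are floored at the smallest positive float so none prints as 0.
* **Per-family GC–Ka table**: families require ≥ 8 homologs with defined
  Ka; raw p plus Benjamini–Hochberg q across families.
* **Principal-component regression**: compositions are centered but not
  scaled (all 20 columns already share the fraction scale; a standardize
  switch exists). Components come from SVD with the sign fixed so each
  component's largest-magnitude loading is positive, making results
  independent of library/LAPACK sign conventions. OLS of Ka on the leading
  6 score columns; PC1 scores are correlated against gene GC. Amino acids
  with |PC1 loading| > 1/√20 (the flat-loading magnitude) form the
  positive/negative PC1 sets. If the composition matrix is rank-deficient
  (it always is at full order: fractions sum to 1) the fit drops to the
  available rank with a warning; at full rank PCR R² equals OLS R².
* **Ridge regression**: predictors standardized; penalty chosen by 5-fold
  cross-validated MSE over a log-spaced grid (10⁻⁴–10²). "Contributing"
  amino acids are those whose |standardized coefficient| exceeds the 95th
  percentile of the max-|coefficient| distribution under response
  permutation (500 permutations). This max-statistic rule controls the
  family-wise false-selection rate at 5% by construction; bootstrap
  percentile intervals were evaluated first and discarded because they
  selected spurious amino acids on ~20% of pure-noise responses even after
  Bonferroni adjustment, whereas the permutation rule was exactly
  calibrated in the same experiment.

## The synthetic-data generator

Each family: an ancestor of i.i.d. sense codons whose base frequencies are
calibrated (by root finding) so the expected GC of the stop-excluded codon
distribution equals the reference GC target — naive conditioning on
non-stop codons would inflate GC by ~1.7 points at GC 0.5 because stop
codons are AT-rich. Each genome then evolves the ancestor independently
(star phylogeny): proposals pick a site uniformly and a replacement base
from the genome's stationary distribution (G and C each at gc_target/2),
stop-creating proposals are rejected, nonsynonymous proposals are accepted
with probability ω, synonymous ones always. Every accepted event is logged
(site, from, to, synonymous flag), so descendants replay exactly from the
ancestor and true per-site rates are known: true Ka = accepted
nonsynonymous events / ancestral NG86 N sites.

Branch length is measured in accepted substitutions per nucleotide site
(count = round(t·L), making truth deterministic). Defaults, chosen once as
the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_codons | 150 | gene length (codons) |
| n_genomes | 30 | target genomes per family |
| gc_span | 0.30–0.70 | mutational GC targets, evenly spaced |
| reference_gc_target | 0.33 | low-GC reference-organism role |
| omega | 0.2 | nonsynonymous acceptance (purifying selection) |
| branch_length | 0.15 | base divergence, accepted subs/site |
| divergence_slope | 0.8 | extra subs/site per unit GC displacement |

The per-genome branch length is `branch_length +
divergence_slope·|gc_target − reference_gc_target|`. The slope is the
generator's mechanism for GC-dependent divergence: over a fixed
evolutionary time, a lineage whose mutational equilibrium sits far from
the ancestral composition fixes more changes than one already at
equilibrium. With a constant ω and a flat branch length the accepted
nonsynonymous count is nearly independent of the GC target, so
reference-anchored Ka would be flat in GC — the slope, not ω, carries the
GC–Ka association. Maximum effective branch length under the defaults is
0.15 + 0.8·0.37 ≈ 0.45 substitutions/site.

What the generator emulates: the GC spread of homologs across genomes, its
coupling to amino-acid composition through the code, purifying selection,
and divergence growing with compositional displacement. What it does not:
indels (homologs are gap-free; alignment handling is exercised by
constructed fixtures), transition/transversion asymmetry, site-rate
heterogeneity, codon-usage selection beyond GC, shared phylogenetic
history (descendants are a star, so homologs are exchangeable — matching
the analysis models, which also treat them as independent), and any
cost-based selection. Passing tests therefore demonstrate that the
estimators and statistics recover a GC-driven signal when it is present by
construction; they do not test robustness to tree structure or to
selection regimes the generator cannot produce.

## Numerical and procedural choices

* CV uses the sample (n−1) standard deviation over mean; errors on n < 2
  or zero mean.
* GC is reported in percent; ΔGC in percentage points; compositions and
  ΔAA as fractions.
* CDS validation strips one terminal stop, rejects internal stops,
  ambiguity codes, and frame errors with position-named messages.
* Alignment tie-breaks: the first alignment in Biopython's deterministic
  traceback order; among equal-scoring best hits, the lexicographically
  smallest subject id. Self-hits (same genome and gene id) are excluded in
  self-comparisons.
* BLAST-tabular best hits: max bitscore, then min E-value, then smallest
  subject id.
* Pipeline outputs are TSV with a fixed float format; summary.json embeds
  a SHA-256 config hash and the seed, and re-runs are byte-identical.
* Family simulations draw from seeds spawned off the study seed
  (`numpy.random.SeedSequence`), so studies are reproducible as a whole
  and per family, in any execution order.
* Analysis problem sizes: the validation study uses 50 families × 30
  genomes × 120 codons for rate-based statistics and 200 families for
  deviation-bin statistics; both are the package's chosen desk-scale
  study conditions.

## Known limitations

* Homologs are treated as statistically independent points (no
  phylogenetically independent contrasts); with real genomes the GC–Ka
  p-values would be optimistic.
* NG86 with Jukes–Cantor correction underestimates divergence under
  strong compositional bias and saturates (flagged) near pS = 3/4, which
  the default study conditions regularly reach at synonymous sites for
  high-GC genomes; Ks is computed but, as in the analyses this package
  supports, not interpreted further.
* In-house orthology mode has no E-values (the E < 10⁻⁵ criterion applies
  only to BLAST-tabular input); identity and coverage thresholds do the
  filtering.
* The feature table's recruitment order, cost, and weight columns are
  transcriptions of their published sources; small differences between
  published variants of these vectors move the feature correlations at
  the second decimal.
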