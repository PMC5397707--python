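# Methods

This note records the statistical definitions implemented in `cubkit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Sequence QC

A coding sequence enters the analysis if, after optional removal of a
terminal stop codon, it (i) is longer than 450 bp (≥ 151 sense codons),
(ii) contains only A/C/G/T, (iii) is an exact multiple of three, and
(iv) has no internal stop codon. "Greater than 450 bp" is read literally
as > 450 (i.e. ≥ 451), applied to the sense sequence after terminal-stop
removal, so that the kept set is idempotent under refiltering. Rejected
records are counted under exactly the first failing rule in the fixed
order length → ambiguity → frame → internal stop. Sequences whose length
is not a multiple of three are rejected because every downstream index is
codon-based; mitochondrial exclusion is list-based (an ID list supplied by
the caller), not sequence-based. Internally coordinates are 0-based and
codon *i* occupies nucleotides [3i, 3i+3).

## Index definitions and conventions

* **RSCU.** `deg(aa) · N(c) / Σ_family N`. Families of absent amino acids
  are *undefined* (NaN), never zero. The three six-fold families (Leu,
  Ser, Arg) are kept whole — not split 4+2 — for both RSCU and ENc,
  matching the 59-codon table convention.
* **ENc (Wright).** Per-family homozygosity `F = (nΣp² − 1)/(n − 1)` for
  families with n ≥ 2; families with F ≤ 0 are not estimable. Class means
  are taken over 2-, 3- (Ile only), 4- and 6-fold families and combined as
  `2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped at 61. A class with no
  estimable family borrows the mean of the estimable class means; the
  value is undefined if fewer than two classes are estimable. Note the
  finite-n correction makes per-gene ENc length-dependent for very short
  genes; the relative ENc deviation is effectively length-invariant only
  once families hold a few dozen codons.
* **GC3s and silent bases.** GC3s runs over third positions of synonymous
  codons only (Met, Trp excluded). X3s uses the classic denominator —
  synonymous codons whose family *offers* an X-ending synonym — so that
  e.g. Lys/Gln/Glu codons do not dilute the pyrimidine fractions; a
  plain-share variant is available via `method="simple"`.
* **CAI (Sharp–Li).** Reference counts are pooled; codons unobserved in
  the reference receive a pseudo-count of 0.5 (configurable) before RSCU,
  keeping every weight positive; `w = RSCU/RSCU_max` per family; the gene
  value is the geometric mean of w over the gene's synonymous codons, Met
  and Trp excluded (their w ≡ 1 carries no information).
* **GRAVY / aromaticity.** Kyte–Doolittle mean hydropathy and the
  Phe+Tyr+Trp residue fraction of the translated protein (Biopython's
  `ProteinAnalysis`).
* **Fop.** Optimal-codon count over all synonymous codons (Met/Trp
  excluded from the denominator).

## Multivariate analysis

The gene × codon matrix holds per-gene relative adaptiveness (per-gene
RSCU divided by the within-family maximum), which shares a common [0, 1]
scale across columns — hence PCA is run on the centred but *unscaled*
(covariance) basis. Cells of families absent from a gene are undefined
and imputed with the column mean, i.e. they contribute nothing after
centring; this retains short genes rather than dropping them. The full
59-codon column set is the default; a `drop-max` option (one codon per
family removed, 41 columns) exists because the column set is a modelling
choice, not a fact of the data. PCA signs are arbitrary, so PC1 is
oriented to correlate negatively with per-gene GC3s (GC3-rich genes at
negative scores), making runs comparable.

The expression-axis test standardises reference-gene scores with the
all-gene mean and SD of a component and labels the component "Expression"
when the mean |z| exceeds 5.17. The threshold is implemented verbatim as
a configurable constant; note that its traditional "only 1.5% of genes"
gloss is hard to reconcile with any sizeable reference class, since a
class holding a fraction f of genes cannot exceed mean |z| =
√((1−f)/f) — with 15 reference genes among thousands the test is
meaningful, with a top-decile class it can never fire.

Index correlation tables default to Spearman rank correlation
(configurable to Pearson), pairwise-complete over undefined entries, with
two-sided p-values; the method used is recorded in the output.

## Diagnostics

The ENc-plot compares observed ENc with Wright's null curve
`2 + s + 29/(s² + (1−s)²)` evaluated at **GC3s** (synonymous third
positions). The relative deviation `(ENc_exp − ENc_obs)/ENc_exp` is
binned in half-open width-0.05 bins anchored at 0. PR2 coordinates use
only the 32 codons of the eight four-codon blocks (Leu → CUN, Ser → UCN,
Arg → CGN; AGR/AGY excluded). The neutrality fit is ordinary least
squares of GC12 on GC3 (not major-axis regression); the OP point
`intercept/(1 − slope)` is reported both as a fraction and ×100, and is
undefined when the slope is 1 within 1e-12.

## Optimal codons

Pools are the top and bottom `floor(0.05 · N)` genes on PC1 (8,620 genes
→ 431 per pool); ties in score break on gene ID. Because PCA signs are
arbitrary, the "high" (expression) pool is the extreme whose mean score
is closer to the reference genes' mean. Each degenerate codon is tested
in a 2×2 chi-square — this codon vs its other synonyms × high vs low
pool — without Yates correction (pool counts are in the hundreds to
thousands; configurable), under Holm's sequential Bonferroni correction
across the 59 codons. The optimality call requires, besides significance
at P < 0.01, a higher within-family frequency in the high pool *and*
high-pool RSCU > 1. The RSCU clause matters in practice: on the bundled
pool counts, AGC is significantly elevated in the high pool yet has
high-pool RSCU 0.95, and only with the clause does the called set match
the published 21-codon set exactly. The family-wide (6×2) test variant
was considered and rejected because the per-codon 2×2 reproduces the
published calls.

Species comparisons divide per-1000 frequencies codon-wise; ratios > 2 or
< 0.5 count as divergent. A codon used by the focal species but absent
from the other is divergent with an undefined ratio; a codon absent from
both is left undefined and not counted.

## Synthetic data: what it emulates, and what not

Amino acids are drawn i.i.d. from an average protein composition
(Swiss-Prot-like frequencies); each CDS starts with ATG, ends with a
single TAA, and passes QC by construction. Lengths are normal with mean
320 and SD 100 codons, clipped at 151 — matching the ~326-codon mean of
the motivating dataset. Synonymous choice under mutation is a
third-position draw: G/C with probability `gc3_target` (default a
per-gene Uniform(0.3, 0.7), mirroring the observed GC3s spread of
roughly 0.50 ± 0.07), uniform within the G/C and A/T alternatives.

The selection regime substitutes the family's designated preferred codon
(default: the C-ending synonym, else G-ending — 18 codons) with
probability `p_g = min(1, s · e_g)`, where `e_g` is a log-normal
expression covariate (sdlog 1.5). The linear-with-saturation response was
chosen over an exponential-saturating one deliberately: the regime must
express *both* of its defining signatures simultaneously — a usage
gradient across the whole expression range (so CAI tracks expression,
Spearman ρ > 0.5) and a thin, extreme reference class (so the 15
top-expression "ribosomal proxy" genes reach mean |z| > 5.17 on PC1). An
early-saturating response drives mid-expression genes to fixation,
inflating the PC1 spread and destroying the z signature. The preset
strength 0.015 places the bulk of genes on the gentle part of the
response and the reference class near fixation.

The neutrality regime draws per-gene GC3 from Uniform(0.25, 0.75) and
interpolates the amino-acid composition between an AT-rich and a GC-rich
pool so that expected GC12 equals `a + b·GC3 + ε` (defaults a = 0.425,
b = 0.11, ε ~ N(0, 0.03) — the slope, OP point and residual scale of the
motivating dataset); unreachable targets raise an explicit error.

What the generator does **not** emulate: amino-acid composition variation
between genes (outside the neutrality coupling), codon autocorrelation
and codon-pair effects, strand asymmetry, isochore structure, paralogy,
and any coupling between expression and GC content. Passing tests on
these data therefore demonstrate the *detectability of the encoded
structures by the pipeline*, not the realism of any particular organism's
codon landscape.

Test problem sizes: the simulation-based checks run at 2,000 genes —
large enough that the mutation regime's mean |relative ENc deviation|
(≈ 0.028, mostly short-gene estimation noise plus the known ~1–2%
mismatch between the sampling model and Wright's approximate curve at
GC3s far from 0.5) sits clearly inside the 0.03 acceptance band, and the
neutrality slope standard error (≈ 0.006) makes the 95% CI check
informative.

## Numerical conventions

Half-up rounding to 2 decimals is applied only when comparing against
published table values (`tests`/`scripts`), never inside the library.
Published values shipped with the package are carried verbatim; the
genome-wide Phe row is internally inconsistent with its own counts
(56781/56843 imply RSCU 1.00/1.00, printed 0.97/1.03) and is excluded
from reproduction checks. PCA uses the deterministic full-SVD solver.
All randomness flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

* Only the standard nuclear genetic code is supported.
* The ENc estimator returns NaN for genes where fewer than two degeneracy
  classes are estimable (very short or compositionally extreme genes).
* The "40 factors" sometimes quoted for adaptiveness PCA column sets is
  not reconstructable from first principles; this package offers 59
  (default) or 41 (`drop-max`) columns.
* Correlation tables reproduce the analysis machinery, but their values
  are dataset-bound; no reference values ship with the package.
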