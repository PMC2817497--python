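# Methods

This note records the models, conventions, and numerical choices behind
`codonbias`, and what the synthetic-data tests do and do not establish.

## Gene inclusion filter

A gene enters the analysis when its codon count — terminal stop included —
is strictly greater than `min_codons` (default 100), its first codon is in
the start set (default {ATG, GTG, TTG}, the common bacterial/actinophage
starts; configurable to strict {ATG}), its last codon is a stop, no
internal codon is a stop, and every base is A/C/G/T. Genes with any
ambiguous base are rejected outright rather than codon-masked so that all
downstream counts stay integral. Rejections carry a single reason code,
assigned in the fixed order BAD_LENGTH → AMBIGUOUS_BASE → TOO_SHORT →
BAD_START → BAD_STOP → INTERNAL_STOP; the kept/rejected sets always
partition the input and filtering is idempotent. GenBank CDS coordinates
are treated as 1-based inclusive at the file boundary (Biopython handles
the conversion); join locations are spliced and complement features
reverse-complemented; fuzzy locations (`<`, `>`) are skipped with a log
entry rather than guessed at.

## Codon-usage indices

The genetic code is fixed to the bacterial/plastid table (NCBI table 11;
sense-codon assignments identical to the standard code). Leu, Ser and Arg
are treated as single six-fold families, not split 2+4 — the family-wide
arithmetic the bundled pooled reference table follows. The 59 synonymously
variable codons exclude Met (ATG), Trp (TGG) and the three stops.

**RSCU.** `RSCU(c) = n_c · k / n_family`. A family with zero total yields
0.0 for all members. In pooled tables Met/Trp are reported as 1.00 and
stops as 0.00 by display convention; in the extreme-group contrast table
the three stop codons are displayed as an ordinary 3-member family
(matching how such two-group tables are conventionally printed) but are
never tested or called.

**Nc.** Wright's estimator. Per family with count n ≥ 2, the homozygosity
`F̂ = (n Σp̂² − 1)/(n − 1)`; F̂ is averaged over the usable families of each
degeneracy class (2-fold: 9 families, 3-fold: Ile alone, 4-fold: 5,
6-fold: 3) and `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`. When the Ile class
is unusable — unobserved, n < 2, or F̂ exactly 0 (possible at small n, e.g.
two Ile codons of different synonyms, which would otherwise make 1/F̄₃
infinite) — it is interpolated as `(F̄₂ + F̄₄)/2`, the usual Wright-style
fallback. If any other class has no usable family or a non-positive mean,
Nc is undefined (NaN) and the gene is excluded from Nc summaries with a
log entry. Sampling noise can push the estimate above the theoretical
ceiling, so values are capped at 61.0; near-uniform inputs therefore
plateau at 61 before the estimator starts to fall under progressive skew.

**Base composition.** GC, GC1, GC2 are computed over all sense codons of a
gene; GC3s and A3s/T3s/G3s/C3s over third positions of the 59 synonymous
codons only, as plain fractions (they sum to 1, and GC3s = G3s + C3s).
Genome-level summaries are unweighted means over genes (not
length-weighted); the choice matters little in practice but is fixed here.

**GRAVY / aromaticity.** Mean Kyte–Doolittle hydropathy (scale taken from
Biopython) and the Phe+Tyr+Trp fraction over encoded residues, stops
excluded.

## Nc plot

The no-selection expectation is `Nc*(s) = 2 + s + 29/(s² + (1−s)²)` for
third-position G+C fraction s ∈ [0, 1]; it satisfies
`Nc*(s) − Nc*(1−s) = 2s − 1` and peaks at s = 0.5 (60.5). Each gene's
deviation `Nc − Nc*` is reported; genes well below the curve carry bias
beyond composition.

## Correspondence analysis

Classical chi-square-metric CA applied to the gene × 59-codon RSCU matrix
treated as a nonnegative data table (the standard codon-usage COA
approach; RSCU rather than raw counts suppresses amino-acid composition).
The matrix is scaled to proportions P with row/column masses r, c; the
standardized residuals `S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` are decomposed
by SVD; principal coordinates are `D_r^{-1/2}UΣ` (genes) and `D_c^{-1/2}VΣ`
(codons); each axis carries σᵢ²/Σσⱼ² of the total inertia. Numerical
conventions: singular values below 1e-12 of the largest are rank-zeroed;
zero-sum columns are dropped with a log entry; a matrix of identical rows
returns zero inertia and all-zero coordinates. Axis signs are fixed by
making the largest-magnitude column loading positive, and axis 1 is
additionally flipped, when per-gene Nc values are supplied, so that its
correlation with Nc is non-negative — biased (low-Nc, G/C-ending) genes
then sit on the negative side, which is the orientation the extreme-group
contrast assumes. Absent families enter as RSCU 0 rather than row-mean
imputation. CA dialects differ in scaling details, so inertia fractions on
real data may differ slightly from other implementations; the package's
axes are pinned in tests against an independent dense eigendecomposition
of the same residual matrix to 1e-9.

## Extreme-group contrast

Groups are the `max(1, floor(fraction · n))` genes (default fraction 0.10)
at each end of axis 1, ties at the boundary broken by lexicographic gene
id. Codon counts are pooled within groups; each codon of a degenerate
family is tested with the 2×2 table [codon vs rest of family] × [left vs
right pool] by Pearson chi-square, df = 1, without continuity correction
and without multiple-testing adjustment (the screen is reported raw, with
the number of tests available to the user; this is also the period-typical
practice of the surveys this workflow reproduces). A per-codon 2×2 test —
rather than a family-wide k×2 test — is what per-codon significance marks
in such tables imply. A codon is called over-represented in a pool when
P < .01 and its RSCU is higher there; codons whose 2×2 table has a zero
margin are reported NS with an undefined statistic.

## Association screens

Pearson r with the two-tailed t-transform p-value
(`t = r√((n−2)/(1−r²))`, as implemented in scipy) plus ordinary
least-squares slope/intercept/r². The grid is 13 screens — Nc vs
C3s/T3s/A3s/G3s, length vs Nc/GC3s, axis 1 vs
GC3s/A3s/T3s/G3s/C3s/GRAVY/aromaticity — run pooled and per genome
(genomes with fewer than 3 genes skipped). Per-genome screens use the
axis-1 coordinates of one pooled CA run by default; genome-specific CA is
possible by running the CA per subset and passing its axis instead.

## tRNA matching

A tRNA inventory is a list of (amino acid, anticodon 5'→3', gene copy
number). Under `strict` pairing a tRNA reads exactly the reverse
complement of its anticodon; `crick` adds position-34 wobble (anticodon G
additionally reads the U-ending codon of the box, anticodon U the
G-ending one). Each record's anticodon is validated against the genetic
code. Modified-base wobble (inosine etc.) is deliberately out of scope: it
is not inferable from gene sequence. No real organism's inventory is
bundled; tests use small synthetic inventories.

## Synthetic data generator

The generator emulates the statistical structure of a multi-phage CDS
collection: 32 genome labels filled round-robin, gene lengths uniform on
[101, 600] total codons (above the inclusion threshold), amino acids i.i.d.
from the pooled amino-acid frequencies of the bundled reference table
(a realistic GC-rich phage background), and two latent classes. Within a
family, codon c is drawn with probability ∝
`exp(β·[third ∈ {G,C}] + γ·[third = C])`. Defaults: low class β = 1.0,
γ = 0.2 (GC3s ≈ 0.75, matching the mid-range of the reference genomes);
high class β = 2.2, γ = 0.8 (GC3s ≈ 0.93 with extra C-preference, like the
most biased genomes); 10% of genes are high-class. Genes always begin with
ATG, contain no internal stop, and end with a uniformly drawn stop, so the
generator's output passes the filter by construction; a companion
malformed-gene generator violates each filter rule exactly once for
negative tests. Randomness is a numpy PCG64 stream per gene, keyed by
(seed, gene index), so earlier genes are byte-stable when more genes are
added.

What the generator does *not* emulate: positional/di-codon
autocorrelation, amino-acid composition differences between classes,
gene-length/bias coupling, operon or strand structure, and tRNA
coevolution. Tests passing on synthetic data therefore establish that the
statistics and their couplings (Nc–GC3s, axis-1 separation, G/C-ending
optimal codons) are computed correctly and recover planted structure — not
that real genomes satisfy the generator's independence assumptions.

## Reference data

Three plain-TSV tables transcribed from a published 32-genome
mycobacteriophage survey ship with the package: pooled codon counts with
printed RSCU, extreme-group pool counts with printed group RSCU, and
per-genome mean/sd Nc and GC3s. One printed group-RSCU entry (AAU, left
pool) is internally inconsistent with its two-fold family sum and is
stored as recomputed from its printed counts (0.10), noted in the file
header. Recomputing Pearson r between the 32 per-genome mean Nc and mean
GC3s values from the printed (2-dp-rounded) means gives r = −0.971; the
survey's own figure, −0.969, was evidently computed from unrounded or
gene-level data that the printed tables do not contain.

## Problem sizes

Default test and example datasets use 60–200 synthetic genes of 101–600
codons, which makes every planted effect (class separation AUC > 0.9,
C-ending enrichment, strong negative Nc–GC3s correlation) detectable while
keeping a full suite run in seconds; the generator scales to arbitrarily
many genes by construction.
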