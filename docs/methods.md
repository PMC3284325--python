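# Methods

This note records the model implemented by `htreeqa`, the numerical and
design choices that were genuinely open, and what the simulator does and
does not emulate.

## Data model and normalization

Genotypes are unphased calls over {0, 1, H, missing}. On load, alleles are
relabelled per marker so that "1" is the minor allele, counting each
homozygous-minor call twice and each heterozygote once over twice the
non-missing sample count; an exact 50/50 tie keeps the input labels
(deterministic, idempotent). Marker indices are 0-based internally,
positions stay 1-based bp, intervals are inclusive at both ends.

Missing data policy: compatibility and tree logic are defined only on
{0, 1, H}, so markers with missing calls are excluded before analysis
(`filter_markers`, default `max_missing = 0`, configurable); missing calls
are never imputed. Samples with a missing *phenotype* are kept for tree
building but dropped from association scoring. Binary traits are accepted
as 0/1 quantitative values; there is no logistic machinery.

## Compatibility decision

Each SNP column expands into the triplet columns S′(0), S′(1), S′(H)
(calls 0, 1, H → (0,0,0), (1,1,0), (1,0,1)). An interval is compatible —
i.e. admits a tristate semi-perfect phylogeny — iff two of the three
columns can be retained per SNP with all retained pairs passing the
four-gamete test. This selection problem is naturally posed as an
integer linear program; because intervals are short in practice and the
decision must be exact, we solve it instead by depth-first search over the
three choices per SNP with (i) a memoized pairwise conflict table shared
across all interval queries on a matrix, (ii) forward checking, and
(iii) domain collapse for heterozygosity-free SNPs (their three choices
impose identical constraints). The search order is fixed — per SNP prefer
retaining {S′(0), S′(1)}, then {S′(0), S′(H)}, then {S′(1), S′(H)},
assigned left to right — so the certifying selection is deterministic.
The first preference reproduces the worked-example tree in which the
homozygous-minor column of the second marker cleanly separates the two
recessive carriers.

Four-gamete counting uses only observed rows (no phantom gametes):
constant columns and length-1 columns always pass, and constant columns
never create edges or constraints.

Maximal intervals: compatibility is hereditary (restricting a certifying
selection certifies any sub-interval), so for each right end v the
smallest compatible left end u(v) is non-decreasing. A two-pointer sweep
per chromosome finds all maximal intervals in O(n) solver calls;
`max_interval_width` (default unbounded) guards pathological inputs.
Whether to enumerate every maximal interval or a sliding subset was open;
we enumerate all — every marker then belongs to at least one interval.

## Tree construction

The selected columns feed a classical perfect-phylogeny construction:
columns are recoded against the first sample's row (complementation does
not change unrooted splits or four-gamete status), constant columns are
dropped, duplicate splits merge onto one multi-labelled edge, and the
remaining columns — pairwise nested or disjoint after recoding — attach
along root-to-leaf paths in order of decreasing carrier count. Rooting at
the first sample rather than at the all-major state is deliberate: an
all-major root is not always consistent with columns that pass only the
unrooted four-gamete test, and every downstream computation uses unrooted
splits only, so the root is a construction detail. Samples whose selected
states equal an internal node's state are attached to that internal node
(where the samples-at-internal-nodes question was open, this choice
matches the narrated placement of the heterozygous sample in the worked
example). A SNP with all three alleles observed contributes two distinct
non-constant splits; with two alleles, one.

## Association testing

Removing x distinct edges yields x + 1 groups; groups must each hold at
least `min_group` samples (default 1 — a real recessive hit can isolate a
handful of carriers, so a higher floor is dangerous). `max_cut` defaults
to 2: examining all possible partitions is exponential in the edge count,
and two cuts already express the three-group patterns (0 / H / 1
carriers) the tristate model exists for; the cap is exposed in
`ScanConfig`.

The partition statistic is the plain ratio of between- to within-group
sums of squares, with no degrees-of-freedom scaling. Because that ratio is
not comparable across different group counts, partitions are ranked by
nominal p-value: the df-scaled one-way ANOVA F(p−1, t−p) tail probability
(parametric mode, requiring t > p), or the fraction of label shuffles
whose ratio reaches the observed one (permutation mode; ties count as
significant so a constant phenotype correctly yields p = 1; an optional
(n+1)/(nPerm+1) correction flag avoids exact zeros). Ties across
partitions break toward fewer removed edges, then lexicographic edge
indices.

Degenerate perfect separation (within-group sum of squares numerically
zero — relative tolerance 1e-12 of the total sum of squares — with
non-zero between) has no finite statistic. Its parametric p is a flagged
sentinel, 5e-324, chosen to sort strictly below any achievable parametric
p-value (those are clipped at 1e-300). Perfect separations therefore
dominate minima identically in observed and permuted scans, and the
genome-wide permutation layer, not the sentinel, is the authoritative
significance source for such hits.

## Genome-wide permutation FWER

Intervals, trees and candidate partitions are computed once per genotype
matrix and reused for every permutation (and, where several phenotypes are
scanned on the same genotypes, across phenotypes — `prepare_scan`).
Each permutation shuffles the phenotype values across individuals, using a
stream spawned deterministically from the master seed, so results are
bit-reproducible and independent of evaluation order. "More significant"
is implemented as permuted-min ≤ observed-min (ties count against the
observed scan: conservative). The significance threshold at level α is
the lower (type-1) empirical α-quantile of the permutation minima; an
interval is reported when its nominal p is at or below that threshold.
The scan is single-threaded; duplicate partitions (overlapping intervals
share splits) are scored once via a content-keyed cache, and all
permutation rows are scored vectorized per partition.

## Phenotype simulator

Additive model: y = √(1−π)·N(0,1) + Q·√(π/(2p(1−p))), Q ∈ {−1, 0, +1}
for homozygous major / heterozygous / homozygous minor, p the *empirical*
minor allele frequency of the causative marker (not a nominal design
value). Var(Q) = 2p(1−p) under Hardy–Weinberg, so the fraction of
phenotypic variance explained by the locus is π — the five study settings
are π ∈ {0.05, 0.1, 0.15, 0.2, 0.25}.

Recessive and overdominant models: Q′ ∈ {0, 1} marks homozygous mutants,
respectively heterozygotes, with coefficient √(π/(2p′(1−p′))) where p′ is
the fraction of homozygous mutants. The coefficient is implemented
exactly in this form, even though for a binary coding the 2 in the
denominator makes the realized explained-variance fraction about π/2
rather than π (and for the overdominant model p′ refers to the homozygous
class while Q′ marks heterozygotes). A `variance_exact` flag substitutes
√(π/(c(1−c))) with c the carrier fraction of Q′, which makes the
explained fraction exactly π; the default keeps the stated form. p or p′
at 0 or 1 is an error (degenerate coefficient).

The causative SNP is drawn uniformly among markers with minor allele
frequency above `maf_floor` (default 0.15) and removed from the analysis
matrix; pre-masking marker indices are retained, and a reported interval
is a true positive when it contains a marker within `window_snps`
(default 50) pre-masking indices of the causative SNP. Precision counts
every reported interval, recall counts replicates whose causative locus
was covered, F1 is their harmonic mean, all with 0/0 → 0.

## Genotype simulator

The source study simulated 170 individuals at 10,000 SNPs but did not
specify the generative model, so the generator here is this package's own
design, built to emulate a partially inbred multiparental panel:

* **Founders.** Eight founder haplotypes whose columns are random clade
  indicators of a per-block random genealogy (blocks have geometric
  lengths, `founder_block_rate = 0.02` per marker, mean 50 markers).
  Within a block, founder columns are mutually four-gamete compatible, as
  they would be in a real pedigree without historical recombination inside
  a small window. Independent random founder alleles would make adjacent
  markers incompatible almost everywhere (with 8 founders all four
  gametes co-occur at ~60% of column pairs) and no multi-SNP compatible
  interval would exist — the tree-consistent construction is what gives
  the genome its block-wise LD.
* **Gametes.** Each individual's two gametes are founder mosaics with
  shared switch points (per-marker switch probability `recomb_rate`,
  default 0.001 ≈ one recombination per thousand markers, matching a
  CC-like density of founder segments). At each new segment the second
  gamete copies the first founder except with a decoupling probability
  calibrated, against the realized founder disagreement rate, to hit the
  target residual heterozygosity `het_target = 0.16` — the level reported
  for partially inbred CC lines. Genotypes are H where the gametes
  disagree; sample-level incompatibilities therefore arise from mosaic
  switch points and founder-block boundaries, the two biological sources
  of local tree breakage.

What the simulator does *not* emulate: genotyping error and missing
calls, allele-frequency spectra from real mutation/drift processes,
linkage-map heterogeneity, multiple chromosomes (one chromosome is
generated; the scan itself handles any number), and selection or
population structure beyond the founder mosaic. Passing tests on these
synthetic data demonstrate correctness and calibration of the machinery,
not field performance on a specific real panel.

## Calibration and problem sizes

Under exchangeable null phenotypes the corrected p-value is discrete at
resolution 1/n_perm and its rejection rule P(corrected ≤ α) has expected
level (⌊α·n_perm⌋ + 1)/(n_perm + 1) — e.g. ≈ 0.059 at α = 0.05 with 100
permutations — slightly above α, shrinking as n_perm grows. The
calibration suite measures the family-wise rejection rate over 150–200
null replicates on a fixed founder-mosaic matrix (100 samples, 150–200
SNPs, 100 permutations), sizes chosen so the whole suite and the
acceptance script each complete in minutes on one CPU while leaving the
binomial error of the estimate at ~±0.017; the heritability check uses
50,000 Hardy–Weinberg genotypes, where the sampling error of the squared
correlation is ~0.003.

## Known limitations

* Exact backtracking is worst-case exponential in the number of
  heterozygous SNPs per interval; real and simulated panels keep
  intervals short, and `max_interval_width` is the escape hatch.
* Nominal parametric p-values assume within-group normality; the
  genome-wide permutation layer does not, and is the quantity to report.
* `evaluate` counts every significant interval separately, so precision
  is deflated when many overlapping intervals tag one locus; no interval
  merging is attempted.
* No covariates, no kinship/mixed-model correction (by design: the target
  populations lack global structure), no X/Y/mito special-casing.
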