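# Methods notes

This note records the models implemented in `neodup`, the assumptions and
parameter choices behind them, what the synthetic-data generators do and do
not emulate, and the numerical conventions used throughout.

## Divergence estimation (kaks)

Sites and differences follow the unweighted Nei–Gojobori (1986) counting
scheme. For a codon, each position contributes (number of synonymous
single-nucleotide changes)/3 synonymous sites; changes producing stop
codons are counted as nonsynonymous, so synonymous + nonsynonymous sites
always sum to exactly 3 per codon. Between two codons differing at two or
three positions, differences are averaged over the 2 or 6 single-step
pathways, with equal pathway weights and no transition/transversion
weighting; pathways whose intermediates are stop codons are removed from
the average, and a codon pair is skipped (with a warning) if every pathway
is removed. Site totals for a pair of sequences average the two sequences'
per-codon site counts. Proportions are corrected with the one-parameter
Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3), which assumes equal base
frequencies and exchangeabilities; p ≥ 3/4 is reported as saturation
rather than a number.

Codon pairs containing a gap, an ambiguous base, or a stop in either
sequence are excluded *pairwise* (pairwise deletion). Complete deletion
would shrink the comparable region for every pair; pairwise deletion
matches common NG86 implementations and keeps windows comparable. Sliding
windows are specified in nucleotides (default length 150, step 6) but are
snapped to codon boundaries — start rounded down to a codon, length to the
nearest multiple of 3. Windows with Ks = 0 report the Ka/Ks ratio as
missing rather than 0 or ∞; a window longer than the alignment collapses
to one full-length window with a warning.

## Polarization and dating (polarize)

Ancestral states follow strict parsimony: the ancestral base at a site is
the unanimous base among non-missing outgroup orthologs; any disagreement,
or a fully missing outgroup column, makes the site ambiguous (a value, not
an error — ambiguous sites are retained in the per-site table but excluded
from lineage counts). Majority-rule consensus is deliberately not offered.
Per variable site between the duplicates: the copy differing from the
ancestral state carries the substitution; a shared derived state absent
from the outgroups maps to the pre-duplication branch; two different
derived states yield one substitution on each lineage.

Synonymous/nonsynonymous classification replaces the substituted position
with the ancestral base inside the observed codon of the carrying lineage.
Codons with several assigned substitutions are classified
substitution-by-substitution along a stepwise path from the ancestral
codon, choosing an ordering that avoids stop-codon intermediates, and are
flagged `multi_hit` in the output.

Duplication age is estimated as age = t_split · (1 − shared/total), where
`shared` counts parent-lineage synonymous substitutions also carried by
the duplicate (fixed between speciation and duplication) and `total` is
all parent-lineage synonymous substitutions since speciation. This linear
reading assumes a constant synonymous clock on the parental lineage and is
an *interpretation* — the source analyses report the resulting age (3.5
Myr from 2 of 6 shared) without an explicit formula. The default
t_split = 5.25 Myr is the speciation time that reproduces that age under
this formula, consistent with the ~5 Myr split of the focal species from
its sister; it is a configurable parameter, not a constant.

The lineage-asymmetry test is a two-cell goodness-of-fit χ² against an
equal split with df = 1 and no continuity correction, matching how such
counts are conventionally tested.

## Population genetics (popgen)

π is the mean pairwise difference per site with pairwise deletion of
missing data; a site enters the surveyed length L only if ≥ 90% of alleles
are called. Watterson's θ_w = S/(a1·L) with a1 = Σ 1/i. Sites with more
than two alleles contribute to π (pairwise counting handles them
naturally) but are excluded from S-based statistics with a warning —
the source data are essentially biallelic and the statistics' variance
formulas assume the infinite-sites model.

Tajima's D uses the 1989 constants; Fu & Li's D*/F* use the 1993
singleton-based statistics with the corrected variance terms in the form
used by standard population-genetics software, and the unstarred D/F
variants use derived singletons polarized by an outgroup; Fay & Wu's
H = π − θ_H with θ_H = Σ 2ξᵢi²/(n(n−1)) over the unfolded spectrum.
Polarized statistics use fully-called columns whose outgroup base occurs
in the sample; other columns are dropped. All SFS statistics return
"undefined" (None) when S = 0. The test suite verifies each statistic
against a separately coded transcription of the published constant tables
(to 1e−9) and against neutral-simulation means, since no independent
Fu–Li implementation was available as an oracle.

Empirical nulls replace theoretical distributions: the quantile of a focal
value x in a genome-wide set of N values is
(#{v < x} + 0.5·#{v = x} + 0.5)/(N + 1) (mid-rank, never exactly 0 or 1),
and a two-tailed call at level γ requires the quantile to fall in either
γ/2 tail. This absorbs genome-wide demographic distortion of the SFS at
the cost of assuming the focal locus is exchangeable with the null set.

For the MK test, divergence cells start from the lineage-assigned
substitutions; a population site whose derived allele is at frequency
≥ 0.99 with the ancestral allele absent among called alleles is treated as
fixed (divergence), never as polymorphism — the fixation threshold mirrors
panels in which a substitution is carried by ~99% of alleles with the
remainder uncalled. Remaining segregating sites are classified against the
major-allele codon context. NI and α are undefined when a denominator
count is zero; the Fisher p is computed regardless.

## Contingency statistics (assoc)

The Yates-corrected 2×2 statistic is Σ (max(|O−E|−0.5, 0))²/E — the
clamped form, so perfectly proportional tables give exactly 0. The
comparison of down/up differentially-expressed-gene counts between the two
mutants is modeled as a 2×2 table (regulation direction × mutant) with
Yates correction; this is a reverse-engineered reading — the source
describes the test only as "equal number of interacting genes", which as a
two-cell goodness-of-fit does not reproduce the printed statistics,
whereas the 2×2 Yates construction reproduces both (18.511 and 26.863).
Fisher's two-tailed p sums hypergeometric probabilities ≤ that of the
observed table, the convention of mainstream implementations; the test
suite checks it against exact rational enumeration.

## Phenotypes (pheno)

Trait effects are summarised by maximum-likelihood Gaussian fits (mean and
population SD, divisor n); zero variance is flagged as degenerate rather
than an error. Genotype comparisons use the two-sided Wilcoxon rank-sum
test, exact when the smaller sample has ≤ 8 observations and the pooled
sample is tie-free, otherwise the tie-corrected normal approximation.
No multiple-testing correction is applied by default (raw p-values are
reported, matching the source analyses); Holm adjustment can be applied
downstream.

PCA is an eigendecomposition of the covariance matrix of mean-centred
traits with divisor n — the R `princomp` default, which the 58.8%/14.5%
variance split of the original trait table tests. Traits are in
heterogeneous units (mm, counts, days), so covariance PCA weights
high-variance traits more; a `scale=True` option provides the
correlation-matrix variant for sensitivity analysis. Rows with any missing
trait are dropped (complete-case) so every individual contributes to every
component and centroids are comparable. Component signs are fixed by
making each component's largest-magnitude loading positive; PED is
invariant to this choice. Experiments grown separately (e.g. T-DNA vs
CRISPR lines) must be analysed as separate PCA spaces; PED is meaningful
only within a space.

## Synthetic data (synth)

The generators provide truth-known inputs for every stage; each takes one
seed, uses a single numpy generator, and serialises a `SimTruth` record
that fully determines expected estimator values.

- `simulate_duplicate_pair` is substitution-count-driven: requested
  (synonymous, nonsynonymous) counts for the new-gene lineage, parental
  lineage, and shared pre-duplication branch are planted at distinct codon
  sites, each classified by construction, so polarization has an exact
  truth. Outgroups carry the ancestral state plus private changes at
  otherwise untouched codons; with ≥ 2 outgroups those sites resolve as
  ambiguous, never as false assignments. No in-frame stop codons are ever
  emitted. A rate-driven alternative, `simulate_pair_omega`, proposes
  Poisson numbers of single-nucleotide changes and accepts nonsynonymous
  ones with probability ω, so the expected estimated Ka/Ks equals ω.
- `simulate_population` draws S ~ Poisson(θ·a1) segregating sites with
  derived-allele counts i sampled with P(i) ∝ 1/i — the expected neutral
  SFS without simulating genealogies. This reproduces E[π] = E[S/a1] = θ
  and mean-zero Tajima's D, which is what the calibration tests use it
  for; it does *not* reproduce the correlation structure (linkage) among
  sites, the variance inflation of real coalescent genealogies, or
  recombination, selection and demography. Passing tests therefore show
  estimator correctness and mean-level calibration, not robustness to
  those features of real data. Near-fixed sites are planted at the
  requested frequency with the remaining alleles missing ('N'), so the
  ancestral allele is absent, as in the motivating resequencing panel.
- `simulate_null_genes` tabulates per-gene statistics over independent
  neutral loci for empirical-null construction; `simulate_phenotypes`
  draws multivariate-Gaussian trait blocks per genotype, matching the
  Gaussian effect-distribution assumption of the phenotype analysis.

Default study-scale conditions used by the acceptance script: a 300-codon
duplicate pair carrying (5 syn, 22 nonsyn) new-lineage, (4 syn, 3 nonsyn)
parental, and (2 syn, 0 nonsyn) shared substitutions — the published
substitution history; neutral calibration at n = 20, θ = 5 per locus,
2,000 replicates; estimator recovery at 5,000 codons (ω = 0.5) and 5,000
individuals per genotype. These sizes give Monte-Carlo error comfortably
inside the documented tolerances (±0.1 on mean D and on recovered ω and
PED).

## Numerical conventions and limitations

Coordinates are 0-based half-open internally; 1-based positions appear
only in human-readable per-site tables. Undefined statistics are `None`
(JSON null), never NaN or sentinel numbers. Ks = 0 ratios are missing, not
infinite. χ² p-values use the survival function of the χ² distribution;
Fisher and rank-sum p-values are clamped to [0, 1].

Known limitations: no maximum-likelihood dN/dS (branch/site codon models);
no probabilistic ancestral reconstruction — strict parsimony understates
uncertainty when outgroups are few or divergent; the duplication-dating
formula assumes a linear synonymous clock and is sensitive to the small
shared/total counts it uses; the MK framework assumes polymorphism and
divergence sample the same mutational classes; empirical-null inference
assumes exchangeability of the focal gene with the genome-wide set; and
the SFS-based simulator is not a substitute for coalescent machinery when
variance (rather than mean) behaviour of the statistics matters.
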