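# Methods

## The problem

Independent forward genetic screens of the same phenotype produce candidate
tables that differ in three ways that matter statistically: the significance
measure (p-value vs FDR, as chosen by each screen's authors), the calling
threshold, and — most importantly — coverage, from a few dozen curated genes
to the whole genome. Combining such screens by intersecting hit lists
discards every gene that only one screen could have seen. `screenrank`
treats each screen as a *partial ranked list* over a fixed gene space and
combines the lists by rank aggregation, so a gene's evidence is weighed only
against the screens that actually interrogated it.

## Base rankers

For a screen with tested gene set T and significance measures m(g) ∈ [0, 1],
the base ranker assigns

- rank 1…k to the genes with m(g) < α, ascending in m (α = 0.05 by
  default; the threshold is strict),
- rank k+1 to every other tested gene, including tested-but-unmeasured genes
  from screens that publish only a hit list plus library membership,
- no rank to untested genes.

Ties in m are broken by larger effect size when the screen provides one,
otherwise by harmonized symbol order; both choices are arbitrary but fixed,
so rankings are reproducible. The construction guarantees the rank law used
throughout: significant ranks are exactly a permutation of 1…k and
`rank ≤ k` is equivalent to "identified by this screen".

## Geometric Borda aggregation

Given base rankers R₁…R_K over a gene space of size N, each gene g tested by
at least one screen receives

    s(g) = exp( (1 / |S_g|) · Σ_{i ∈ S_g} log r_i(g) ),   S_g = screens testing g,

and the aggregated list sorts ascending in s. Untested screens contribute
nothing: "not tested" (NA) is a different statement from "tested but not
significant" (k+1), and imputing a space-sized rank N+1 for every untested
screen crushes genes from low-coverage screens (measured on the synthetic
default study, N+1 imputation halves planted-positive recovery). The
imputation variant remains available (`impute_untested=True`) for
sensitivity analysis, as do arithmetic, median and quadratic-mean baselines.

Scores are accumulated in log space over *sorted* ranks so they are immune
to overflow and bit-identical regardless of the order screens are supplied
in. Score ties are broken by (screens-identified desc, screens-tested desc,
symbol) — corroboration first, then determinism. Genes never significant in
any screen stay in the full table flagged by `n_screens_identified = 0` but
are excluded from the exported candidate list: their only evidence is the
sentinel k+1.

## Overlap analysis

Per gene: the number of screens that tested it, the number that identified
it (rank ≤ k), and the percentage identified-of-tested (integer-rounded in
exports, full precision internally). Multi-screen candidates are the genes
identified by ≥ `min_count` screens (default 2), sorted by corroboration,
with known malignancy-driver genes filtered from the final list only — the
driver filter is not applied before aggregation.

## Overrepresentation analysis

For a candidate list of size n drawn from a background of size M, a term
with K members in the background and overlap x with the candidates gets the
one-sided upper tail p = P(X ≥ x), X ~ Hypergeom(M, K, n), via
`scipy.stats.hypergeom.sf`, then Benjamini–Hochberg adjustment across the
tested terms. The background defaults to the supplied gene space restricted
to genes annotated in at least one term (the usual ORA convention);
`annotated_background=False` uses the whole space. Candidates outside the
background are dropped with a logged count; g:Profiler-style g:SCS
correction is deliberately not reproduced — BH is the standard, documented
substitution.

## Preranked GSEA

The ranking metric is score(g) = −log10(adjusted p) · avg_log2FC, sorted
descending, with adjusted p = 0 clamped to 1e−300 so the metric stays
finite, and score ties broken by symbol (documented because the enrichment
score can depend on hit order). The enrichment statistic is the weighted
Kolmogorov–Smirnov running sum: at a hit the sum rises by |score|^p · Z⁻¹
(Z normalizes hit increments to +1; p = 1 by default, p = 0 recovers the
classic KS statistic), at a miss it falls by 1/(N − m). ES is the
maximum-magnitude deviation, with exact ± ties resolved to the positive
deviation; the running sum starts and ends at zero by construction. If every
hit score is exactly zero the weights degenerate and equal weights are used
instead.

The null is gene-label permutation — random same-size gene sets — the only
null available for preranked input. With n same-sign null scores of which c
are at least as extreme as |ES|,

    nominal p = (1 + c) / (1 + n),      NES = ES / mean(|same-sign null ES|).

The add-one estimator keeps p positive and is the standard permutation
convention; conditioning on sign mirrors the positive/negative split of
mainstream GSEA implementations and is what keeps the null calibration
honest (≈ 5% of pure-null runs below p = 0.05; the acceptance script
measures this). The FDR q is Benjamini–Hochberg across the evaluated sets,
and a single-set run reports q = nominal p — the NES-histogram FDR of GSEA
v4 needs many sets and is deliberately not reproduced. A small exhaustive
mode enumerates every placement (capped at 2·10⁵ combinations) for oracle
testing.

`simple_de` supplies the metric's inputs for synthetic runs: per-gene
two-sided Wilcoxon rank-sum between the two groups (vectorized
`scipy.stats.mannwhitneyu`; constant rows fall back to p = 1), BH
adjustment, and avg_log2FC = log2((mean₁ + ε)/(mean₂ + ε)) with ε = 1e−9. It
is a minimal two-group test, not a reimplementation of any single-cell DE
framework.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults define the study conditions:

| parameter    | default                              | meaning |
|--------------|--------------------------------------|---------|
| n_genes      | 2000                                 | gene-space size |
| n_screens    | 6                                    | number of screens |
| coverages    | 0.0125, 0.05, 0.1, 0.5, 1.0, 1.0     | fraction of the space each screen tests (25-gene library … whole genome) |
| n_true       | 30                                   | planted positives |
| beta_a       | 0.1                                  | alternative p ~ Beta(a, 1), skewed small |
| detect_prob  | 0.6                                  | per-screen chance a tested positive draws from the alternative |
| expression   | 20/group, shift 2.0, σ 0.5 (log2)    | two-group log-normal counts, planted set shifted in group T |

Beta(a, 1) with a < 1 is the standard skewed-small alternative for p-value
simulation; `detect_prob` models between-technology heterogeneity — a gene
can be a genuine hit under transposon mutagenesis and invisible to a CRISPR
knockout screen, which is exactly why most corroborated genes in real
multi-screen comparisons are identified by only one or two screens. Nulls
(and undetected positives) draw Uniform(0, 1). Coverage masks are uniform
random subsets. Expression counts are log-normal with per-gene baselines;
the planted shift of 2 log2 units over 20 samples per group makes the
planted set separable by design. All generators are pure functions of
(config, seed): the truth, screen and expression streams are independent
children of the config seed, so `simulate_screens` and `simulate_expression`
agree on the planted positives without sharing state.

What the generator does *not* emulate: correlated hits (pathway structure),
screen-specific measure distributions (all screens emit p-like uniforms),
non-uniform library design, count-level noise (sgRNA/insertion-site data),
and mouse/human ortholog divergence (symbols are abstract). Passing tests
therefore demonstrate the statistical machinery, not robustness to these
real-data features.

One consequence worth stating: with these defaults a tested positive is
significant in a given screen with probability
0.6·0.05^0.1 + 0.4·0.05 ≈ 0.465, so about 20% of planted positives are
significant in *no* screen and cannot appear in the candidate list at all.
Recovery of planted positives in the top 60 of the aggregated list is
bounded by that detectability ceiling; the acceptance script reports the
measured value (about two-thirds pooled over ten seeds) rather than the
ceiling.

The enriched annotation term uses weighted sampling without replacement to
bias membership toward planted positives at a stated odds ratio — a
Wallenius-style approximation, adequate for a fixture generator.

## Symbol harmonization

Trim whitespace, uppercase — nothing else. The analysis compares mouse-style
(`Aak1`) and human-style (`AAK1`) symbols and tables that mix both;
case-folded identity is the stand-in for true ortholog mapping, which is out
of scope. Harmonization is idempotent, and loaders never silently drop a
record: duplicates, out-of-space genes and unparseable rows are logged or
raised.

## Problem sizes and determinism

The test suite and the acceptance script run the statistical checks at desk
scale: 1,000 random screens for the rank law, 200 instances ≤ 50 genes × 6
screens against the brute-force aggregation oracle, every hypergeometric
configuration with background ≤ 15 against exact enumeration, 200 pure-null
GSEA runs (400-gene expression matrices, 199 permutations) for calibration,
and 20 planted-shift runs for the FDR convention — sizes chosen so the whole
suite completes in seconds while the binomial bounds on the calibration
checks stay meaningful. Every stochastic component takes an explicit seed;
identical seeds reproduce byte-identical outputs.

## Known limitations

- The geometric NA-ignoring rule is a documented choice; other rank
  aggregation packages differ in their treatment of partial lists, so
  orderings need not match any particular external tool.
- The GSEA FDR is BH across evaluated sets, not the NES-histogram FDR; the
  two agree in the single-set regime this pipeline typically runs in but
  will differ for large collections.
- `simple_de` ranks genes well for simulation purposes but makes no claim of
  matching any published single-cell DE pipeline.
- ORA power on aggregated candidate lists is limited when candidates are
  dominated by per-screen false positives, as in the synthetic default study
  (the planted-enrichment term is detectable in the expression arm long
  before the ORA arm).
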