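# Methods

## Scope and data model

`metscreen` analyzes paired in vivo pooled CRISPR knockout screens: for each
replicate mouse, a metastasis sample (lung, optionally liver) is compared
against the primary tumor of the *same* mouse.  Counts travel as
tab-separated sgRNA × sample tables (header `sgRNA`, `gene`, then one
integer column per sample); sample metadata (cell line, mouse, tissue, and
optionally a per-mouse lung preference) lives in a separate YAML file.  Gene
reports use 1-based `neg|rank` / `pos|rank` columns with rank 1 the most
significant.  Raw-read processing (alignment, guide counting) is out of
scope; the pipeline starts from counts.

## Normalization

Median-of-ratios: each sample's size factor is the median over sgRNAs
detected in every sample of its count divided by the across-sample
geometric mean of that sgRNA; normalized values are raw counts divided by
the size factor (pseudocount 0 by default).  When no sgRNA is detected
everywhere — possible in severely bottlenecked organ samples — the code
falls back to total-count factors and logs it.  As with any
geometric-mean-referenced scheme, rescaling one sample by *k* changes all
size factors by a common drift of `k^(1/S)`: size-factor *ratios* scale by
exactly *k* and normalized profiles are unchanged up to one common factor,
which is the invariance the tests assert.

## Per-sgRNA model

The mean–variance law `var(μ) = μ + k·μ^b` is fitted on control (primary)
replicates.  Per-sgRNA sample variances are extremely noisy at 4–5
replicates, so sgRNAs are pooled into 20 abundance-quantile bins; within
each bin the mean of per-sgRNA means and of per-sgRNA variances give one
point, and `log(var − mean)` is regressed on `log(mean)` over bins with
pooled variance above the mean.  Fallback to `var = μ + 0.01·μ²` (logged)
occurs with a single control sample, with fewer than 10 sgRNAs showing
var > mean, or when the mean variance/mean ratio is below 1.1 — i.e. the
counts carry no usable overdispersion, as for Poisson-like data.  On
synthetic gamma–Poisson counts with k = 0.05 the fit recovers k within 20%
and b within 0.2 of 2, and doubling all counts leaves b unchanged (the
quadratic law maps onto itself under scaling).

The paired test treats the metastasis value (rounded to the nearest
integer, so tails are exact) as a draw from NB(mean μ, variance var(μ)),
with μ the normalized control abundance plus pseudocount 1 (a zero-mean NB
is degenerate).  Parameterization: size `r = μ²/(var−μ)`; when var ≤ μ the
Poisson tail is used.  `p_high = P(X ≥ t)` is the enrichment
(positive-selection) direction — the one in which suppressor knockouts
move — and `p_low = P(X ≤ t)` the depletion direction.

**Rank construction.** sgRNA ranks are ordered by the exact tail p-value
with ties broken by the continuous z-score `(t − μ)/√var(μ)`, then sgRNA
id.  The z tie-break matters: exact discrete tails tie heavily — every
zero-count metastasis sgRNA has `p_high` exactly 1, and tight in vivo
bottlenecks routinely zero out 10–25% of guides.  Averaging such a block
into one shared fractional rank caps the gene statistic and collapses a
material fraction of null genes onto a single value, which puts an atom at
gene p = 1 and visibly breaks null uniformity (KS 0.05–0.15 in our null
screens).  With z-broken strict ranks a zero is placed according to how
surprising it is (the larger the control mean, the more depleted), gene
blocks remain exchangeable under the null, and gene-level p-values are
uniform (KS 0.01–0.03).  Reported p-values keep the exact-tail convention.

## Gene-level aggregation (α-RRA)

For a gene with m sgRNAs at sorted fractional ranks `r_1 ≤ … ≤ r_m` among
all n sgRNAs, `ρ = min {I_{r_i}(i, m−i+1) : r_i ≤ α}` (regularized
incomplete beta = uniform order-statistic tail), ρ = 1 when no sgRNA lies
in the top-α.  α defaults to 0.05 (α = 1 gives classic cutoff-free rank
aggregation).  Fractional ranks come from the strict `rank_low` /
`rank_high` columns divided by n; for external p-value vectors a
tie-averaged variant (`gene_rra.percentile_ranks`) is provided.

Permutation calibration reassigns the rank vector to genes preserving each
gene's sgRNA count (one shared permutation stream per call, seeded;
n_perm ≥ 100, default 1000) and uses add-one p-values
`(1 + #{ρ_perm ≤ ρ_obs})/(1 + n_perm)`, so p is never exactly 0 and is
valid by construction.  FDR is Benjamini–Hochberg.  On tiny instances the
sampled p agrees with exhaustive enumeration over all rank assignments
within Monte-Carlo error (tested).

**Report ranks.** Genes are ranked by ascending p, then ρ, then the α = 1
aggregation score, then gene id.  The third key exists because with α < 1
a large fraction of null genes shares ρ = 1 exactly; breaking that tie by
id would make tail ranks arbitrary, and the lung-vs-liver filter compares
rank integers in that tail.  The α = 1 score is continuous over the whole
range, so ranks remain informative end to end while never overriding the
primary keys.

Null calibration note: with α < 1 the null distribution of gene p has an
atom of mass ≈ (1−α)^m at 1 *by construction* (genes with no sgRNA in the
top-α).  Whole-distribution uniformity is therefore only a meaningful
statement at α = 1; at the default α the lower tail is what matters and
`P(p < 0.05) ≈ 0.05` holds.  The acceptance tests check exactly these two
statements.

## Replicate integration and hit calling

*Mouse selection:* the k (default 4 of 5) mice with the largest lung
preference, ties by mouse id.  The simulator supplies the ground-truth
preference (lung / (lung+liver) seeded burden); real screens must supply an
imaging- or burden-derived value in the metadata.

*Essentiality:* per gene, the smallest FDR-adjusted p of the chosen
direction (default `pos`: enrichment of suppressor knockouts) across
selected mice; score `−log10(min adj. p)`, so "highest score" and
"smallest adjusted p" coincide; final rank ascending in min adjusted p.
Adjusted p-values saturate at the permutation resolution
(`1/(n_perm+1)` before BH), so rank ties are broken by smallest raw p,
then smallest ρ, then gene id — without this, floor-tied genes would be
ordered alphabetically.  A gene absent from a mouse counts as p = 1 there
(logged).

*Concordance:* genes significant (min adj. p ≤ threshold, default 0.05) in
both cell lines; combined rank is the worse of the two per-line ranks
(demands strength in both lines); the top-k list intersects the per-line
top-k sets and keeps the k best combined ranks.

*Lung-vs-liver filter:* a gene passes in a mouse iff
`neg_rank(lung) > neg_rank(liver)` and `pos_rank(lung) < pos_rank(liver)`
(read numerically on 1-based ranks: less depleted and simultaneously more
enriched in lung than liver); overall passing requires all replicate mice.
Passing genes are ordered by Fisher-combined lung p-values of the chosen
direction across replicates.  Fisher was chosen as the combination rule
(the min-p and rank-sum alternatives order the saturated top ties less
informatively); the direction is a flag because either reading of
"negative p-values" may be wanted.  Under a pure null the two inequalities
are each ≈ Bernoulli(1/2) per mouse and positively correlated (both say
"more enriched in lung"), so the expected all-replicates pass count is
bounded near `n/2^R` rather than the `n/4^R` an independence argument
would give; the null test asserts the empirically valid bound.

## Simulator

Stages, all driven by `numpy.random.SeedSequence(seed)` spawned streams
(stream 0: plasmid library; stream 1+i: everything in mouse i):

1. plasmid abundance per sgRNA ~ log-normal(σ = 0.5), normalized;
2. founder cells per mouse: multinomial(cells × MOI, plasmid abundance);
3. primary growth: one gamma multiplier per sgRNA lineage
   (shape 1/d, scale d, d = `growth_dispersion` = 0.2), giving NB-like
   marginals matching the analysis model;
4. organ seeding: per-cell binomial with probability
   `base_seed_prob × effect(gene)` (effects ≥ 1 multiply seeding for
   planted suppressors); realized seeds resampled down to the organ
   bottleneck when exceeded; a zero-seed organ yields an all-zero sample
   with a warning;
5. metastatic outgrowth: gamma multipliers again;
6. sequencing: multinomial(depth, abundances) per sample.

Defaults are desk-scale study conditions: 2000 genes × 4 sgRNAs, 5 mice,
MOI 0.3, cells per mouse chosen for ≥200× per-sgRNA coverage, lung/liver
base seeding probabilities 0.03/0.01 (lung preference ≈ 0.75, matching the
~70% lung vs ~18% liver tropism of clear cell renal cell carcinoma),
bottleneck 20 000 cells per organ (≈2.5 cells/sgRNA at the default library
— a tight clonal bottleneck with realistic 10–25% guide dropout), depth
300 reads/sgRNA.  Genome-scale sizes are a config choice, not a test
requirement.

What it does **not** emulate: immune editing, copy-number effects on guide
counts, multi-step metastatic cascades, inter-guide efficacy differences,
or PCR jackpotting.  Passing tests therefore demonstrate the statistical
machinery under an NB-like, bottlenecked generative model — not
performance on any particular real screen.

## Benchmarks computed by tests and the acceptance script

* permutation p vs exhaustive enumeration on a 4-gene × 2-sgRNA instance:
  agreement within 3·√(p(1−p)/n_perm) at n_perm = 10 000;
* effect-free screen (1000 genes): gene-level enrichment p uniform
  (KS < 0.05 at α = 1) and `P(p < 0.05) = 0.05 ± 0.02` at α = 0.05;
* planted benchmark (2000 genes, 20 suppressors at lung effect 10, 5 mice):
  ≥ 80% of planted genes inside the top 1% of final ranks (observed: 95 to
  100% across seeds);
* organ specificity (10 lung-specific vs 10 pan-organ planted genes):
  filter pass rate ≥ 80% vs < 20% (observed: 90–100% vs 0%);
* seeded determinism: byte-identical counts and gene reports across runs;
* the closed-form bench formulas (H-score, percent input, 2^−ΔΔCt, tumor
  volume, track statistics) at their hand-checkable values.

## Numerical and degenerate-input choices

* Metastasis values are rounded to integers before tail evaluation; exact
  tails, no continuity correction.  At t = μ the score is 0 and neither
  tail is significant; the upper tail can sit marginally below 1/2 by the
  right-skew of the NB (median ≤ mean) — inherent to exact discrete tails.
* All report ranks and orderings have total, deterministic tie chains
  ending in gene/sgRNA id; outputs are invariant to input row order.
* `h_score` uses exact rational arithmetic of bin counts (no intermediate
  percentage rounding).  `percent_input` implements the plain printed
  formula; an input-dilution correction is available behind an explicit
  `dilution_factor` argument.  Track velocity is accumulated path length
  over elapsed time (mean speed), the convention of the usual
  chemotaxis-tool outputs; directionality is 0 for a stationary track.
* Tumor volume warns (but computes) when width exceeds length.

## Known limitations

* The NB variance law is global (one (k, b) per screen); organ samples are
  typically more dispersed than the primary-tumor controls it is fitted
  on, so per-sgRNA p-values in metastasis samples are anti-conservative.
  The permutation stage absorbs this at gene level — gene p-values stay
  calibrated because sgRNA ranks remain exchangeable across genes — but
  per-sgRNA p-values should not be interpreted in isolation.
* Permutation resolution floors p-values at 1/(n_perm+1); top hits tie at
  the floor and are ordered by the documented tie chain.  Raise `n_perm`
  when absolute p-values (rather than ranks) matter.
* The essentiality min-p across mice is an anti-conservative summary by
  design (it rewards one strong mouse); it mirrors the screen's
  "representative score" definition and is not a calibrated p-value.
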